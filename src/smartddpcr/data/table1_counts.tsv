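snp_id	gene	genomic_location	n_heterozygotes	n_ai	k_risk	k_prot
rs3731217	CDKN2A	chr9:21984661	50	17	11	6
rs4132601	IKZF1	chr7:50470604	142	29	17	12
rs2239633	CEBPE	chr14:23589057	42	32	19	13
rs7089424	ARID5B	chr10:63752159	61	35	20	15
rs10764338	PIP4K2A	chr10:22866892	19	9	4	5
rs3824662	GATA3	chr10:8104208	37	19	10	9
rs3731249	CDKN2A	.	17	17	14	3
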