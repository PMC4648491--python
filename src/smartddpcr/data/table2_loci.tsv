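scna_type	peak_name	cytoband	chrom	start	end	assoc_cancer_traits	tumor_types
amplification	TERC	3q26.2	3	169389459	169490555	Bladder;glioma;melanoma;multiple myeloma	BLCA,LUAD,LUSC,UCEC
amplification	FGFR3	4p16.3	4	1778797	1817427	Bladder	BLCA,GBM,OV,UCEC
amplification	TERT	5p15.33	5	1287704	1300024	Basal cell carcinoma;bladder;breast;lung adenocarcinoma;glioma;melanoma;prostate;testicular germ cell	BLCA,CRC,GBM,HNSC,LUAD,LUSC,OV,UCEC
amplification	EGFR	7p11.2	7	55075808	55093954	Glioma	BLCA,BRCA,GBM,HNSC,LUAD,LUSC
amplification	MYC	8q24.21	8	128739772	128762863	Bladder;breast;CLL;CRC;ovarian;prostate;renal cell carcinoma	BLCA,BRCA,GBM,KIRC,OV,UCEC
amplification	CCND1	11q13.3	11	69464719	69502928	Breast;multiple myeloma;renal cell carcinoma	BRCA,LUAD
amplification	KDM5A	12p13.33	12	1	980639	CRC	BRCA,CRC,HNSC,LUAD,LUSC,OV
amplification	CCNE1	19q12	19	30306758	30316875	Bladder	BLCA,BRCA,GBM,LUSC,OV,UCEC
deletion	IKZF2	2q34	2	211542637	214143899	Breast;non-small cell lung cancer	BLCA,LUSC,UCEC
deletion	LINC00290	4q34.3	4	178911874	183060693	Multiple myeloma;non-small cell lung cancer	BLCA,GBM,KIRC,LUAD,LUSC,OV,UCEC
deletion	5q15	5q15	5	73236070	114508587	Breast;CRC;GBM;gallbladder;Hodgkin's lymphoma;prostate;Wilms tumor	CRC,LUAD,LUSC
deletion	CDKN2A	9p21.3	9	21865498	22448737	ALL;basal cell carcinoma;breast;CLL;glioma;nasopharyngeal carcinoma;melanoma	BLCA,BRCA,CRC,GBM,HNSC,KIRC,LUAD,LUSC
deletion	9p21.2	9p21.2	9	27572512	28982153	Endometrial	UCEC
deletion	RAD51B	14q24.1	14	68275375	69288431	Breast;prostate	BRCA,CRC,OV
deletion	15q12	15q12	15	1	32929863	Bladder;CRC;multiple myeloma	BLCA,LUSC
deletion	22q13.32	22q13.32	22	48026910	51304566	Endometrial;Pancreatic	BLCA,GBM,LUAD,OV,UCEC
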