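# Demonstration cohort: duplexed SNP assay + genomic control assay over a
# mixture of planted somatic states.  All randomness derives from `seed`.
snp_assay_id: snp_demo
control_assay_id: control_demo
droplet_volume_ul: 0.00085
n_droplets: 15000
n_replicates: 2
seed: 20151117
samples:
  - {sample_id: C01, tissue: constitutional, control_conc: 820, clones: [[1.0, 1, 1, 2]]}
  - {sample_id: C02, tissue: constitutional, control_conc: 640, clones: [[1.0, 1, 1, 2]]}
  - {sample_id: C03, tissue: constitutional, control_conc: 910, clones: [[1.0, 1, 1, 2]]}
  - {sample_id: C04, tissue: constitutional, control_conc: 450, clones: [[1.0, 1, 1, 2]]}
  - {sample_id: C05, tissue: constitutional, control_conc: 760, clones: [[1.0, 1, 1, 2]]}
  - {sample_id: C06, tissue: constitutional, control_conc: 580, clones: [[1.0, 1, 1, 2]]}
  - {sample_id: C07, tissue: constitutional, control_conc: 700, clones: [[1.0, 1, 1, 2]]}
  - {sample_id: C08, tissue: constitutional, control_conc: 880, clones: [[1.0, 1, 1, 2]]}
  # unaltered tumors
  - {sample_id: T01, tissue: tumor, control_conc: 750, clones: [[1.0, 1, 1, 2]]}
  - {sample_id: T02, tissue: tumor, control_conc: 620, clones: [[1.0, 1, 1, 2]]}
  - {sample_id: T03, tissue: tumor, control_conc: 840, clones: [[1.0, 1, 1, 2]]}
  # clonal hemizygous deletions (protective or risk allele lost)
  - {sample_id: T04, tissue: tumor, control_conc: 700, clones: [[1.0, 1, 0, 2]]}
  - {sample_id: T05, tissue: tumor, control_conc: 560, clones: [[1.0, 0, 1, 2]]}
  # subclonal hemizygous deletion, f = 0.5
  - {sample_id: T06, tissue: tumor, control_conc: 800, clones: [[0.5, 1, 0, 2], [0.5, 1, 1, 2]]}
  # subclonal homozygous deletion, f = 0.4 (copy loss without AI)
  - {sample_id: T07, tissue: tumor, control_conc: 730, clones: [[0.4, 0, 0, 2], [0.6, 1, 1, 2]]}
  # clonal copy-neutral LOH toward the risk allele
  - {sample_id: T08, tissue: tumor, control_conc: 680, clones: [[1.0, 2, 0, 2]]}
  # subclonal CN-LOH, f = 0.5
  - {sample_id: T09, tissue: tumor, control_conc: 770, clones: [[0.5, 2, 0, 2], [0.5, 1, 1, 2]]}
  # clonal trisomy with risk-allele gain (proportion ~0.667, CN 1.5)
  - {sample_id: T10, tissue: tumor, control_conc: 640, clones: [[1.0, 2, 1, 2]]}
  # tetraploid shift with 3:1 risk:protective (proportion 0.75, CN 2)
  - {sample_id: T11, tissue: tumor, control_conc: 590, clones: [[1.0, 3, 1, 2]]}
  # near-zero template: excluded by the low-concentration QC rule
  - {sample_id: T12, tissue: tumor, control_conc: 2, clones: [[1.0, 1, 1, 2]]}
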