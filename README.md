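# smartddpcr

Toolkit for droplet-digital-PCR (ddPCR) assessment of tumor allelic
imbalance and the somatic copy-number states behind it:

- **`smartddpcr.droplet`** — droplet partition simulation for duplexed
  FAM/VIC SNP assays plus a genomic-control assay, and Poisson quantitation
  of absolute concentration (copies/µL) from positive-droplet counts, with
  Wilson-interval confidence bounds.
- **`smartddpcr.ai`** — replicate merging, risk-allele proportion
  (`conc_risk / (conc_risk + conc_prot)`), three-sigma threshold calibration
  from constitutional heterozygotes, low-concentration QC exclusion, and
  per-sample allelic-imbalance calls.
- **`smartddpcr.pai`** — exact one-sided binomial test (majority-direction
  tail, null p = 0.5) for preferential allelic imbalance, and cohort
  summaries (counts, percentage, p-value).
- **`smartddpcr.copystate`** — control-normalized copy number, closed-form
  forward models for deletion / CN-LOH / trisomy / tetraploid states as a
  function of the clonal fraction, and least-squares state classification
  with ambiguity flagging.
- **`smartddpcr.agreement`** — Lin's concordance correlation coefficient
  (population moments, Fisher-z CI), Bland–Altman bias/limits, and Sanger
  peak-height proportions.
- **`smartddpcr.scan`** — overlap of recurrent SCNA peak regions (1-based
  inclusive, GISTIC-style) with GWAS-catalog SNPs by position or mapped
  gene, plus controlled-vocabulary cancer-type matching and summaries.
- **`smartddpcr.io` / `smartddpcr.fixtures` / `smartddpcr.cli`** — headered
  CSV/TSV dialects, packaged fixtures (published cohort counts, the
  16-locus candidate table, a deterministic demo cohort) and the umbrella
  CLI.

## CLI

All subcommands run end-to-end on packaged fixtures with no downloads.

```sh
smartddpcr demo --outdir demo_out            # simulate -> call-ai -> pai-test -> copy-state
smartddpcr simulate --config cohort.yaml --seed 1 --out wells.csv
smartddpcr quantify --wells wells.csv --out conc.tsv
smartddpcr call-ai --wells wells.csv --samples samples.csv --snp snp_demo --out calls.tsv
smartddpcr pai-test --calls calls.tsv --out summary.tsv
smartddpcr copy-state --wells wells.csv --snp-assay snp_demo --control-assay control_demo --out states.tsv
smartddpcr agreement --x states.tsv --y mlpa.csv --out agreement.json
smartddpcr scan --regions scna.tsv --catalog gwas.tsv --out candidates.tsv
```

Exit codes: `0` success, `2` validation error, `3` degenerate-statistics
warning escalated under `--strict`. Logs go to stderr (`--verbose`).

### Well CSV dialect

`well_id, sample_id, assay_id, n_total, n_fam_pos, n_vic_pos,
droplet_volume_ul` — one row per well; FAM carries the risk allele, VIC the
protective allele; the control assay uses FAM only. Unknown columns are
preserved on round-trip.

## Notes

- Droplet volume defaults to 0.00085 µL (configurable); allele proportions
  are volume-invariant.
- The binomial tail is taken from the majority direction by default;
  `direction="risk"` gives the strict a-priori risk-direction tail.
- A fraction `f` in the copy-state forward models is the share of cells
  carrying the event; the gain (trisomy) curve coincides with the
  tetraploid 3:1 curve at half the fraction, and such degeneracies resolve
  to the fewest-event model.
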