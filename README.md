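# snpherit

Estimation and partitioning of the phenotypic variance tagged by common
SNPs, in the GREML tradition: SNP QC, genetic relationship matrix (GRM)
construction, AI-REML variance components with boundary handling,
per-chromosome and genic/intergenic partitioning, a GWA scan with the
theta_P p-value-enrichment summary, and a polygenic cohort simulator
that makes every stage testable end to end without external data.

## Layout

- `snpherit.synthetic_data` — polygenic genotype/phenotype simulator
  (HWE genotypes, length-proportional SNP placement, per-component
  architectures, related pairs, age/sex/cohort nuisance structure).
- `snpherit.qc_grm` — SNP QC (missingness > 5%, MAF < 0.01, exact HWE
  p < 1e-6), GRM estimation, greedy unrelated-subset selection
  (relationship cutoff 0.025).
- `snpherit.phenotype_prep` — age adjustment by OLS and z-scoring
  within cohort x sex groups.
- `snpherit.reml` — AI-REML with EM fallback for one or many GRM
  components; SEs from the inverse AI matrix, h2 ratios by the delta
  method, likelihood-ratio tests against the 50:50 chi2 boundary
  mixture, constrain-at-zero-and-refit boundary handling.
- `snpherit.partitioning` — per-chromosome and region partitions,
  across-trait aggregation, variance-vs-DNA-length regression,
  equal-SNP-per-chromosome subsampling.
- `snpherit.gwa_theta` — per-SNP linear-regression scan, variance
  explained by window-pruned genome-wide-significant SNPs, theta_P and
  its correlation with h2 estimates over a threshold grid.
- `snpherit.stat_utils` — z-tests between independent estimates,
  boundary-zero probability, R^2 sampling SE.
- `snpherit.io` — PLINK bed/bim/fam, GCTA-convention GRM text/binary
  files, phenotype/result TSVs, YAML-configured pipeline, CLI.

## CLI

```sh
snpherit simulate --n 2000 --m 20000 --traits 10 --h2 0.3 --seed 1 --out cohort
snpherit qc --bfile cohort --out cohort_qc
snpherit grm --bfile cohort_qc --out cohort_grm
snpherit prune --grm cohort_grm --out keep.tsv
snpherit adjust --pheno cohort.pheno.tsv --out adjusted.tsv
snpherit reml --grm cohort_grm --pheno adjusted.tsv --out estimates.tsv
snpherit gwa --bfile cohort_qc --pheno adjusted.tsv --trait trait1 --out scan.tsv
snpherit partition --bfile cohort_qc --pheno adjusted.tsv --trait trait1 --out parts.tsv
snpherit stats z-diff --a 0.449 0.083 --b 0.316 0.046
```

`snpherit pipeline --config run.yaml` chains all stages; see
`snpherit.io.pipeline.RunConfig` for the YAML keys (paths, QC
thresholds, relatedness cutoff, threshold grid, seed).

Note on the relatedness cutoff: 0.025 is calibrated for GRMs built from
hundreds of thousands of SNPs. On small simulated panels the GRM's
sampling noise (SD ~ 1/sqrt(m)) exceeds it and pruning will remove most
samples — scale the cutoff accordingly.

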