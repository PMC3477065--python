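# paircnv

CNV-aware paired expression analysis of matched tumor pairs — built around
the situation of advanced ovarian cancer, where each patient contributes a
primary ovarian tumor and a matched peritoneal metastasis profile, and where
copy-number differences between the two lesions drive much of the
expression divergence.

The package addresses a specific statistical failure mode of matched-cohort
studies: a copy-number dosage effect carried by only a subset of patients
*averages to insignificance* when all patients are pooled. For a gene with
copy number `c` against the diploid baseline, the dosage model predicts a
linear expression ratio of `c/2` — a single-allele gain (copy 3) is a
1.5-fold change, i.e. +log2(1.5) ≈ 0.585 on the log2 scale, and a
single-copy loss (copy 1) is −1. If three of nine patients carry the gain,
the pooled mean paired difference is only 3·0.585/9 ≈ 0.195, below common
selection thresholds; stratifying patients by their CNV state at each gene
recovers the full effect. The identity behind this is exact: the pooled
mean equals the n-weighted average of stratum means.

## What it does

* **Synthetic matched-pair cohorts** (`paircnv.cohort`) with planted ground
  truth: CNV segments whose per-patient copy state shifts metastasis
  expression by `log2(c/2)`, metastasis-age groups (early/mid/late) with
  decreasing numbers of truly divergent genes, and a good/poor prognostic
  panel with a planted direction-concordance rate.
* **Paired differential expression** (`paircnv.paired_de`): per-patient
  differences (metastasis − primary, the primary is the baseline),
  two-sided one-sample t, signed linear fold changes (d ≥ 0 → 2^d,
  d < 0 → −2^(−d)), BH adjustment, and the two reporting modes —
  global (|fold| ≥ 1.5, p < 0.01) and per-group (|fold| ≥ 2, FDR < 0.2).
* **CNV integration** (`paircnv.cnv_integration`): probes are mapped to CNV
  segments by full encompassment (probe interval contained in the segment),
  patients stratified per gene into amplified/deleted/normal, strata with
  ≥ 3 patients tested separately and contrasted with the pooled analysis.
* **Paired-difference PCA** (`paircnv.paired_pca`): covariance-mode PCA of
  the patients × genes difference matrix, k-means grouping on the top 3
  components, groups named early/mid/late by decreasing divergence.
* **Prognostic concordance** (`paircnv.prognostic`): good/poor panel genes
  classified up/down by the sign of their mean paired difference; the four
  cells tested with a 3-d.f. goodness-of-fit chi-squared (a 2×2
  independence variant is also exposed).
* **Over-representation** (`paircnv.enrichment`): right-tailed Fisher's
  exact / hypergeometric upper-tail `P(X ≥ k | N, K, n)` against any GMT
  collection, BH-adjusted.
* **Pipeline & CLI** (`paircnv.pipeline`, `paircnv.cli`): `paircnv
  simulate|de|cnv|pca|prognosis|enrich|all`, flat YAML config, seeded and
  bit-reproducible, JSON manifest per run.

## Worked example

The numbered scripts under `analysis/` run the whole study on the reference
synthetic cohort (9 patients, 2,500 genes, noise SD 0.2, seed 1):

```sh
python analysis/01_simulate_cohort.py
python analysis/02_global_paired_de.py
python analysis/03_cnv_stratification.py
python analysis/04_pca_metastasis_groups.py
python analysis/05_prognostic_concordance.py
python analysis/06_enrichment.py
```

Script 03 prints:

```
360 probe sets fully encompassed by CNV segments (2140 outside CNVs)
  amplified-stratum mean difference: +0.566 (dosage prediction +0.585)
  deleted-stratum mean difference:   -1.000 (dosage prediction -1.000)
  separation summary (|log2| >= 0.4 selection):
     amp_separated: n= 304  mean diff +0.612
     del_separated: n= 360  mean diff -1.000
     no_separation: n= 360  mean diff -0.141
            no_cnv: n=2140  mean diff -0.010
```

The stratified means land on the dosage predictions while the *same genes*
pooled over all patients (`no_separation`) average to −0.14, and genes
outside CNVs sit at zero — the attenuation-by-averaging effect the
stratification exists to undo. Script 04 recovers the three planted
metastasis-age groups exactly (ARI = 1.00) and shows the divergence
gradient in per-group DE counts (early 128 up / 150 down; mid 13 up /
18 down; late 0/0). Script 05 classifies 166 detectable prognostic genes into cells
{good-up 67, good-down 17, poor-up 15, poor-down 67} — concordant fraction
0.807 against the planted rate 0.8, goodness-of-fit chi² = 62.7 on 3 d.f.
(p ≈ 1.5e-13). Script 06 finds the planted early-group program enriched in
the early DE list (q ≈ 1e-7) while all random sets stay null.

## Layout

```
src/paircnv/      library: cohort, io_formats, paired_de, cnv_integration,
                  paired_pca, prognostic, enrichment, pipeline, cli, plotting
analysis/         numbered narrative drivers writing under results/
tests/            pytest suite (unit, property and end-to-end checks)
scripts/          acceptance recomputation
docs/methods.md   model, parameters, and design notes
```
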