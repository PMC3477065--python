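# Methods

## The model

The package analyses matched tumor pairs: for each patient one primary
lesion and one metastasis, profiled as normalized log2 expression over a
common probe set. The unit of every statistic is the within-patient paired
difference `d_gp = met_gp − prim_gp` for gene `g` and patient `p`, with
the primary tumor as baseline. Three planted mechanisms generate
divergence in the synthetic cohorts, and three analyses are built to
detect them:

1. **Copy-number dosage.** A gene at copy number `c` in the metastasis
   (against a diploid primary) has mean paired difference `log2(c/2)`:
   +0.585 for a single-allele gain (copy 3, a 1.5-fold change), −1 for a
   single-copy loss, capped at −10 for homozygous loss (finite arithmetic
   in place of −∞). Copy states are integers; "amplified" means copy > 2
   and "deleted" copy < 2. The state attached to a CNV record is the sign
   of the metastasis-versus-primary copy difference, since the contrast
   measured is metastasis − primary.
2. **Group divergence.** Patients belong to metastasis-age groups
   (early/mid/late); each group carries its own set of truly shifted genes
   with signed effects of `de_effect` log2 units applied to all of that
   group's metastasis samples. Group sizes decrease in planted divergence
   from early to late.
3. **Prognostic direction signal.** A panel of good/poor-labelled genes is
   shifted in all metastases, in the label's favorable direction (good up,
   poor down) with probability `concordance_rate` and against it
   otherwise.

Noise is Gaussian on the log2 scale, independently per gene and sample —
the standard log-normal microarray assumption; the generator is silent on
probe-level artefacts by design (see Limitations).

## Key parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `n_patients` / `group_sizes` | 9 = 3+3+3 | patients | matched-pair cohort with three equal metastasis-age groups |
| `n_genes` | 2,500 | probe sets | desk-scale genome; one probe per gene |
| `n_segments` × `genes_per_segment` | 12 × 30 | — | 360 CNV genes, ~14% of the array |
| `frac_amp`, `frac_del` | 1/3, 1/3 | proportion | exactly 3 amplified, 3 deleted, 3 neutral patients per segment, so every stratum is testable at `min_patients=3` |
| `amplified_copy` / `deleted_copy` | 3 / 1 | copies | single-allele gain and loss, folds 1.5 and 0.5 |
| `noise_sd` | 0.2 | log2 | per-sample noise; paired differences then have SD ≈ 0.28 |
| `n_de_per_group` | (600, 250, 80) | genes | decreasing early ≫ mid ≫ late; sized so the paired-difference PCA separates the three groups cleanly (detected DE counts at n = 3 pairs understate true divergence by an order of magnitude, so planted truth must be larger than any post-threshold count) |
| `de_effect` | 1.0 | log2 | a 2-fold true shift, typical of clearly divergent genes |
| `n_prognostic`, `prognostic_effect`, `concordance_rate` | 193, 0.5, 0.8 | — | panel of the size survival signatures typically have; a modest shift with strong but imperfect direction concordance |
| `min_patients` | 3 | patients | a stratum is tested only with ≥ 3 patients' data; applied per stratum (the stricter reading) and configurable |
| `min_abs_log2` | 0.4 | log2 | 1.32-fold selection inside CNVs — just under the 1.5-fold single-allele prediction, so dosage-driven strata clear it |
| DE thresholds | 1.5-fold & p<0.01 (global); 2-fold & FDR<0.2 (group) | — | the low global fold cutoff is deliberate: a single-allele gain predicts only 1.5-fold |

## Numerical and procedural choices

* **Encompassment.** A probe inherits a patient's segment state only when
  its interval is fully contained in the segment (0-based half-open
  coordinates throughout; strand ignored). Abutting same-state segments of
  one patient are merged first, so a probe spanning their shared boundary
  counts as contained in the union; segments separated by any gap are not
  merged — the conservative reading of containment in a single segment.
  Opposite-state segments both fully covering a probe raise an error
  rather than picking a winner.
* **Signed fold.** `d ≥ 0 → 2^d`, `d < 0 → −2^(−d)`: magnitude is always
  ≥ 1 and sign encodes direction, so "≥ 1.5-fold" filters symmetrically.
* **Zero-variance probes** are flagged (p = 1) and excluded from calling,
  never silently dropped.
* **Pooled vs stratified.** The pooled mean equals the n-weighted mean of
  stratum means exactly; the test-suite asserts it to 1e-12. Segment-level
  aggregation is the mean of probe-level stratum statistics.
* **PCA.** Covariance mode (genes centered, not scaled — nothing suggests
  correlation-mode), full SVD, with each component's sign fixed by making
  its largest-magnitude loading positive; scores are then reproducible
  across runs and platforms. Grouping is explicit k-means (k = 3, seeded,
  `n_init=10`) rather than eyeballing the 3-D plot; identical patients
  make the partition seed-dependent and set a `degenerate` flag. Cluster →
  early/mid/late naming is by descending mean divergence.
* **Concordance test.** Default `gof4`: the four good/poor × up/down cells
  against equal expected proportions, 3 d.f. — the structure consistent
  with a 3-d.f. chi-squared on four cells. The 2×2 independence test
  (1 d.f., no continuity correction) is exposed as an alternative because
  the choice between the two is genuinely open; results label which was
  used. Ties (exact zero mean difference) are excluded and reported, not
  randomly assigned — reproducibility over an unstated convention.
* **Detectability** is a minimum log2 intensity: a gene must stay above
  the matrix-wide 5th percentile in every sample (configurable).
* **Enrichment** is the plain hypergeometric upper tail (≡ right-tailed
  Fisher), BH-adjusted across the collection, default selection q < 0.25;
  the background defaults to all genes on the array.
* **Determinism.** One top-level seed is fanned out per stage; reruns are
  bit-identical apart from the manifest timestamp.

## What the generator does and does not emulate

It emulates: matched-pair structure, log2-scale intensities, dosage
scaling of expression by per-patient CNV state, patient-specific CNV
heterogeneity (random patients per segment), subgroup structure with a
divergence gradient, and an imperfect prognostic direction signal. It does
not emulate probe-level intensity artefacts, normalization residuals,
batch effects, tumor purity/stromal contamination, correlated noise
between neighboring genes, multi-mapping probes, or overlapping CNV calls
within one patient. Passing tests therefore demonstrate that the
*statistical machinery* recovers planted truth under its own model
assumptions — not that those assumptions hold for any real cohort.

## Problem sizes

The reference cohort is 9 patients × 2,500 genes with 12 CNV segments —
sized so every stage, the full test-suite, and the acceptance
recomputation run in seconds while keeping ≥ 2,000 genes outside CNVs
(enough for the near-zero no-CNV average to be a meaningful check) and
≥ 100 genes per amplified/deleted category. Replicate-based calibration
tests use 100–200-gene cohorts over 100 seeds.

## Known limitations

* Recovery guarantees are calibrated to the default noise (0.2 log2) and
  effect sizes; much noisier data or weaker effects shift power, and the
  per-group mode at 3 pairs has little power by construction (the late
  group is expected to yield zero calls).
* Gene-level operations key on gene symbol; multi-mapping probes must be
  resolved by the annotation producer (readers reject duplicate probe
  IDs).
* The enrichment stage implements the plain Fisher/hypergeometric
  statistic; curated knowledge-base scores (EASE-style adjustments,
  network algorithms) are out of scope, and any GMT collection can be
  supplied instead of the synthetic stand-in.
* k-means grouping assumes the chosen k; no cluster-number selection is
  attempted (k = 3 reflects the three-group design).
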