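# Methods

This note records the models, conventions, and numerical choices behind
`splicestrat`, and what the synthetic-data tests do and do not establish
about real cohorts.

## Isoform quantification from junction counts

A junction is a closed 1-based interval over the excised intron (first and
last intronic base), the convention of recount3-style junction exports.
Quantification is **exact key matching** on (chrom, start, end, strand):
an isoform's expression in a sample is the sum of read counts over its
discriminating junctions, with junctions absent from the matrix
contributing zero and opposite-strand rows never counting. Positional
overlap is deliberately not used — a discriminating junction is an exact
donor–acceptor pair, and near-miss coordinates usually denote a different
splice event.

Log expression is log₁₀(count + 1). The pseudocount of 1 makes
log(0) = 0, keeps counts on their natural scale for large values, and is
exposed as a parameter. The published coordinate pairs for the two PIK3R1
junctions and for the two variant-analysis regions differ by one base at
the boundaries (donor/acceptor-inclusive vs -exclusive ambiguity) and by
interval orientation; we use each set verbatim in its own context
(quantification vs region classification) rather than silently
reconciling them, and the parser normalizes reversed intervals by
swapping with an explicit warning. Junction strings tolerate en dashes,
unicode minus signs, and digit-grouping commas, since all three occur in
printed coordinates.

STAR `SJ.out.tab` input uses column 7 (uniquely mapping reads) by
default; `count_column="total"` adds multimappers. Rows with strand
code 0 (undefined) are skipped with a warning. Duplicate junction keys
within one file are an error, not summed: duplicates indicate corrupt
input.

## Stratification rules

Tumors are grouped per cancer type:

- **Mean split (p85α):** threshold = arithmetic mean of tumor log₁₀
  expression within the cancer type; `high` iff strictly above. Ties at
  the mean go to `low`; on continuous log data this is a measure-zero
  choice. The split is computed per cancer type (configurable) because
  baseline expression differs across tissues, and on the log scale
  because that is the scale of every plotted and tested quantity.
- **Zero split (p55α):** `low` iff the raw discriminating-junction count
  is exactly 0. This rule presupposes a point mass at zero, which is what
  the junction data show for an isoform absent from most normal tissue —
  and which the synthetic generator reproduces with a zero-inflated
  negative binomial.

Race strings are mapped case-insensitively onto AA (African American) and
EA (European American) via a configurable synonym table; anything else is
retained under `NA-other` and flagged excluded from between-group tests
rather than dropped, so cohort accounting stays complete.

## Group statistics

All test statistics are computed from their definitions; SciPy supplies
only distribution functions (normal, F, studentized range) and midranks.

- **Wilcoxon rank-sum.** Statistic W = sum of midranks of the first
  group. Exact mode enumerates the null distribution of W by dynamic
  programming over k-subsets of {1..N} (requires no ties, combined
  n ≤ 12 by default); the two-sided p is the null mass at least as far
  from the mean as observed. The approximation uses tie-corrected
  variance n₁n₂/12 · [(N+1) − Σ(t³−t)/(N(N−1))] and a 0.5 continuity
  correction; zero variance (all values identical) returns p = 1. The
  tumor-vs-normal comparison is unpaired: group sizes differ in every
  cancer type.
- **One-way ANOVA.** F = MS_between/MS_within with df (k−1, N−k). Zero
  within-variance is handled explicitly (p = 1 when means agree, p = 0
  when they differ). Protein-by-group comparisons use one-way ANOVA of
  low vs high, matching the displayed two-group contrasts.
- **Tukey–Kramer post-hoc.** q = |mᵢ−mⱼ| / √(MSW/2·(1/nᵢ+1/nⱼ)) against
  the studentized range with k groups and N−k df; for k = 2 this reduces
  exactly to the pooled t-test.
- **2^−ΔΔCt.** ΔΔCt = (Ct_target − Ct_ref)_case − (Ct_target − Ct_ref)_control.
- No multiple-testing correction is applied by default across cancers or
  proteins; Benjamini–Hochberg is available behind a config switch.

## Survival analysis

- **Kaplan–Meier:** right-continuous product-limit estimator; censorings
  tied with events remain in the risk set for those events.
- **Log-rank:** at each distinct event time, observed events per group
  are compared with the hypergeometric expectation d·n_g/n; the k-group
  statistic is v'V⁻v over the first k−1 groups (pseudo-inverse for
  safety), χ² with k−1 df. All-censored input returns p = 1 with a
  warning.
- **Cox regression:** Newton–Raphson on the partial likelihood with the
  Efron tie correction (default; Breslow by flag — Efron is the default
  of the R `survival` package and coincides with Breslow on tie-free
  data). Covariates are centered internally for conditioning; risk-set
  sums are suffix cumulative sums over the time-sorted data. Convergence:
  max |score| < 1e−9, ≤ 100 iterations, with step-halving guarded by a
  slack relative to |log L| so float noise at the optimum cannot trigger
  spurious halving. A coefficient passing |β| > 20 is reported as a
  monotone-likelihood (separation) error naming the covariate. Wald CIs
  are β ± 1.96·SE. With one binary covariate and no ties, the score test
  at β = 0 equals the log-rank χ² exactly; the suite enforces this
  identity to 1e−8 as a cross-module oracle.
- **Encodings:** age continuous (years); sex, race, smoking, alcohol
  one-hot against a stated reference (first alphabetical unless
  configured); AJCC stage collapsed to early (I/II) vs advanced (III/IV)
  since a single stage contrast is reported. Missing covariates:
  complete-case deletion with the dropped count recorded per model.
  Proportional hazards is assumed, not tested; that is a known
  limitation.

## Variant analysis

Region membership is closed-interval containment on both bounds (no
convention was available to prefer half-open). The two isoform regions
overlap at a single coordinate, so "shared" variants sit exactly on that
boundary; shared variants are counted in both regions' totals, and their
rsIDs are listed separately. Consequence vocabulary is frozen to a
gnomAD-style list plus `other`; unknown strings are downgraded to `other`
with a warning, never dropped. The coding-SNV annotator translates the
affected codon before and after substitution with the standard genetic
code and emits HGVS p. notation (`p.Trp6Cys`, `p.(=)` for synonymous,
`Ter` for gained stops, `p.Met1?` for a lost start); a brute-force oracle
in the tests retranslates the entire mutated CDS and diffs the protein.

## Synthetic cohorts

Defaults define the study conditions exercised by the tests: per cancer,
100 tumors and 100 normals; p85α ~ NB(mean 150, size 8) in normals with a
−1 log₂ tumor shift; p55α zero-inflated NB with zero probability 0.8 in
normals vs 0.4 in tumors and positive mean 20 (size 5); race mixture
AA 0.20 / EA 0.75 / other 0.05; exponential survival with baseline hazard
1/1500 per day and log-hazard terms 0.5 for low p85α (HR ≈ 1.65), 0.02
per year of age, 0.7 for advanced stage, 0.2 for AA; uniform censoring on
[0, 3000] days with a 10-year administrative horizon; protein effects of
up to ±0.8 SD between p55α groups. These magnitudes are typical of a
well-expressed junction in bulk RNA-seq and of pan-cancer clinical
effect sizes; the survival model is exponential so closed-form checks
(KM vs exp(−λ₀t)) are possible, with the p85α group entering the hazard
through the same mean-split label the analysis recovers.

Randomness is one stream per component (junctions, clinical, survival,
protein), spawned from the single seed via hashed `SeedSequence` keys, so
identical configs are byte-reproducible and extending one component never
perturbs another. The planted variant fixture emits variants at
deterministic positions inside each region's exclusive part (shared
plants on the overlap coordinate) so the expected tally is exact by
construction, and includes a Trp→Cys coding-SNV example.

What the generator does **not** emulate: library-size and batch effects,
correlated junction noise, non-proportional hazards, informative
censoring, real allele frequencies, or TCGA's missing-data patterns.
Passing tests therefore establish correctness of the estimators and the
plumbing under the stated models, not robustness to those real-data
complications, and the published cohort-level hazard ratios and variant
totals are not recomputation targets — they require the original TCGA,
RPPA, and gnomAD cohorts.

## Problem sizes in the test suite

Monte-Carlo calibration uses 10,000 replicates for Wilcoxon (n = 25/25)
and ANOVA (3 × 20), 5,000 for log-rank (n = 200/200); Cox recovery uses
200 replicates at n = 300 with ~20% censoring; direction recovery runs
the pipeline over 200 generator seeds at n = 100/100. These sizes give
Monte-Carlo standard errors comfortably inside the asserted bands
(e.g. ±0.002 on a 0.05 rejection rate at 10,000 reps) while keeping the
whole suite around a minute of compute.
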