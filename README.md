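# splicestrat

Pan-cancer analysis of alternative-first-exon isoform switching from
splice-junction read counts, built around the two regulatory-subunit
isoforms of *PIK3R1*: the full-length **p85α** and the shorter splicing
variant **p55α**.

## The problem

*PIK3R1* encodes the p85 regulatory subunit of PI3K, a central node of the
PI3K/Akt pathway. Its alternative first exon produces p55α, whose first
exon splices onto the same downstream acceptor as p85α. Because each first
exon excises a different intron, each isoform has a **discriminating splice
junction** — a donor–acceptor pair found in that isoform only — and the
number of RNA-seq reads spanning that junction measures the isoform alone:

- p85α: `chr5:68281007-68292258:+` (hg38, first/last intronic base)
- p55α: `chr5:68290835-68292258:+` (same acceptor, different donor)

The package quantifies both isoforms per sample from junction count
matrices (recount3-style TSV or STAR `SJ.out.tab`), stratifies tumors into
expression groups, and runs the downstream comparisons a pan-cancer study
needs:

- **Expression:** raw junction counts and log₁₀(count + 1) per isoform;
  tumor-vs-normal Wilcoxon rank-sum (exact enumeration for small samples,
  tie-corrected normal approximation otherwise); one-way ANOVA of
  normal vs African-American-tumor vs European-American-tumor groups;
  Tukey–Kramer post-hoc; 2^−ΔΔCt fold changes for qRT-PCR validation.
- **Stratification:** p85α split at the per-cancer mean of tumor log
  expression (`high` iff value > mean); p55α split at zero
  (`low` iff its junction count is exactly 0 — the count distribution has a
  point mass at zero).
- **Survival:** Kaplan–Meier product-limit curves, k-group log-rank tests
  with hypergeometric variance, and multivariate Cox proportional-hazards
  regression (Efron ties, Newton–Raphson) for overall survival (OS) and
  progression-free interval (PFI), adjusting for age, sex, race, stage,
  smoking and alcohol history; forest-style HR tables with 95% CIs.
- **Variants:** classification of population variants into the p85α
  (`5:68,281,006-68,290,834`) and p55α (`5:68,290,834-68,292,259`) GRCh38
  regions, per-consequence-class tallies, shared-variant detection, and a
  coding-SNV annotator producing HGVS p. strings (e.g. c.18G>T →
  `p.Trp6Cys`).
- **Synthetic cohorts:** a seeded generator producing junction matrices,
  clinical tables, survival outcomes, RPPA-like protein tables, and
  planted variant fixtures with the statistical structure above, so the
  whole pipeline is testable without any downloads.

The core statistics (Wilcoxon, ANOVA, KM, log-rank, Cox partial
likelihood) are implemented from first principles and cross-checked in the
test suite against scipy, statsmodels, and lifelines as independent
oracles.

## Worked example

Simulate a cohort (100 tumors / 100 normals, p85α shifted down one log₂
unit in tumors, p55α expressed in 20% of normals vs 60% of tumors) and run
every stage:

```bash
splicestrat simulate --seed 1 --outdir demo/data
cat > demo/cfg.yaml <<EOF
junction_path: demo/data/junctions.tsv
clinical_path: demo/data/clinical.csv
protein_path: demo/data/protein.csv
variant_path: demo/data/variants.tsv
seed: 1
EOF
splicestrat run-all --config demo/cfg.yaml --outdir demo/results
```

`demo/results/diffexp.csv` then contains:

```
cancer isoform  n_tumor  n_normal  statistic      p_value               method  direction
  BRCA    p85a      100       100     5996.5 4.009983e-23 normal_approximation tumor_down
  BRCA    p55a      100       100    11786.0 1.813493e-06 normal_approximation   tumor_up
```

i.e. the pipeline recovers the planted pattern — the full-length isoform
significantly **down** in tumors and the splicing variant **up** — with
the Wilcoxon rank sum of the tumor group as the test statistic.
`logrank.csv` reports the group-survival contrasts (here the low-p85α
group progresses faster: PFI χ² = 8.22, p = 0.0041), and `cox.csv` holds
the adjusted hazard ratios, e.g. for OS stratified by the p85α mean split:

```
           covariate       hr   ci_low  ci_high  p_value stars
                 age 1.016574 0.992020 1.041735 0.187593
          group[low] 1.299318 0.792808 2.129426 0.298875
stage_band[advanced] 1.909145 1.119384 3.256108 0.017595     *
```

Each row is a covariate level versus its reference (high expression,
female, European American, early stage, non-smoker, non-drinker), with
Wald 95% confidence bounds and star notation at the 0.05/0.01/0.001/0.0001
tiers. `variant_tally.csv` holds the region × consequence-class counts
and `shared_variants.csv` the rsIDs falling in both isoform regions.

The same stages are importable as functions (`splicestrat.quantify_isoforms`,
`splicestrat.cox_fit`, ...) for notebook use.

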