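# dyadnet

Stratified psychometric network analysis of longitudinal dyadic
questionnaire cohorts.

## The problem

When a child receives a serious diagnosis, both parents are assessed
repeatedly with the Kellner Symptom Questionnaire (SQ): four symptom
subscales (Anxiety, Depression, Somatisation, Hostility) and four
well-being subscales (Relaxation, Contentedness, Physical Well-Being,
Friendliness).  The sampling unit is the *dyad* — a mother–father couple —
followed at three time points (t1, t2, t3).  Such cohorts are small (tens
of couples), suffer role-specific attrition (typically fathers dropping
out after the first assessment), and the raw data are usually private.

`dyadnet` provides the full analysis chain for this design, plus a
synthetic-cohort generator with planted ground truth so every stage is
testable without access to any real cohort:

1. **Classical statistics** — Kolmogorov–Smirnov normality screening,
   one-way repeated-measures ANOVA over the three assessments with Tukey
   HSD post hocs, mother–father one-way ANOVAs, comparison of subscale
   means against a published control norm (mean ± 1 SD), and an a priori
   power analysis for the bivariate correlation test.
2. **Network estimation** — per role × time stratum, a pairwise mixed
   graphical model over the 8 continuous subscales and the dichotomous
   child-sex variable, estimated by nodewise L1-penalized regressions
   (Gaussian for subscales, logistic for child sex) with 10-fold
   cross-validated penalty selection, a √(log p / n) coefficient
   threshold, and conservative AND-rule edge aggregation.  A missing edge
   means conditional independence given all other variables.
3. **Network description** — node predictability (R² for continuous
   nodes; CC/nCC/CCmarg accuracy decomposition for the categorical node),
   strength and weighted betweenness centrality (edge length = 1/|w|,
   Dijkstra shortest paths), case-resampling bootstrap stability of both
   indices, walk-trap community detection cut at maximum modularity,
   Fruchterman–Reingold layouts with a shared cross-stratum "average
   layout", and node sizes encoding percent change from the first
   assessment.

## The model in brief

For each stratum with data matrix X (n dyads × 9 nodes), node j is
regressed on all others:

- continuous j:  ẑ_j = Σ_k β_jk z_k  with penalty λ‖β_j‖₁ (z-scored data),
- categorical j: logit P(y_j = 1) = β_j0 + Σ_k β_jk z_k with the same
  penalty,

λ chosen per node to minimize 10-fold cross-validated loss over 50
log-spaced values from λ_max down to 10⁻³λ_max, coefficients below
τ = √(log p / n) set to zero.  Edge (j, k) exists iff β_jk ≠ 0 **and**
β_kj ≠ 0; its weight is the mean absolute standardized coefficient and,
for continuous pairs, carries the shared sign (sign conflicts are dropped
and logged).  The power analysis inverts the Fisher-z power function of
the correlation test (bias correction atanh r + r/(2(n−1)), t-based
critical correlation) to find the minimal detectable r.

## Worked example

```bash
dyadnet run-all --seed 7 --outdir run7
dyadnet report --outdir run7
```

runs the default synthetic study — 23 enrolled couples, 7 fathers lost
after t1 — through the whole pipeline (about 2½ minutes; the bootstrap
dominates) and prints:

```
# Cohort network analysis run (dyadnet 0.1.0)

Status: **ok**

## Cohort
- enrolled dyads: 23
- complete-case dyads: 16
- dropped dyads: 7

## Power analysis
- minimal detectable correlation at n=16, alpha=0.05, power=0.8: r = 0.640

## Anxiety at first assessment vs control norm
- sample mean 8.34 vs control 4.25 +- 3.53: **above_1sd**

## Networks

| stratum | n | edges | communities | modularity |
|---|---|---|---|---|
| mother_t1 | 16 | 1 | 8 | 0.000 |
| mother_t2 | 16 | 3 | 7 | 0.000 |
| mother_t3 | 16 | 1 | 8 | 0.000 |
| father_t1 | 16 | 0 | 9 | 0.000 |
| father_t2 | 16 | 0 | 9 | 0.000 |
| father_t3 | 16 | 2 | 7 | 0.500 |
```

Reading this: the complete-case filter keeps the 16 couples observed at
all six role × time cells; at n = 16 only effects with r ≳ 0.64 are
detectable at 80% power, and the estimated networks are accordingly very
sparse — the AND rule plus the √(log p/n) threshold keep false edges out
at the cost of sensitivity, which is exactly the regime such studies
operate in.  The simulated t1 Anxiety mean lies above the control norm
band, as the generator's elevated-distress baseline intends.  Full
machine-readable results land in `run7/` (`report.json`, per-stratum
GraphML + edge lists, centrality/predictability/cluster/layout CSVs, the
generating truth in `truth.json`).

The same pipeline runs on real data in the documented long CSV format via
`mode: csv` in a YAML config (`dyadnet run-all --config my.yaml`).

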