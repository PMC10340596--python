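# Methods

This note documents the statistical machinery in `dyadnet`: what is
assumed, what is tunable, what the synthetic generator does and does not
emulate, and where genuinely open design choices were settled.

## Data model

Observations are long-format rows (dyad, parent role, time point, 8 SQ
subscale scores, child sex).  Scores are bounded integers; the default
ranges are 0–17 for the four symptom subscales and 0–6 for the four
well-being subscales (the SQ item counts), configurable because rescored
instruments exist.  The complete-case unit is the **dyad**: a couple
missing any of its six role × time records is excluded entirely, so that
every stratum compares the same couples.  Strata are ordered mother
t1–t3, father t1–t3, columns fixed as the subscale listing followed by
child sex (0 = male, 1 = female).

## Synthetic cohort generator

Because cohorts of this kind are private, the pipeline ships a generator
whose model is exactly the structure the estimator assumes:

- Per stratum, the 8 continuous subscales follow a Gaussian graphical
  model with a **planted sparse precision matrix**; an off-diagonal entry
  −r (unit diagonal) plants partial correlation r exactly.
- Child sex is Bernoulli(½) per dyad and enters designated nodes as a
  centered **location shift** (the conditional-Gaussian equivalent of a
  logistic link between the binary node and its neighbors).  Default:
  +0.6 latent SD on Somatisation.
- Couple and time coupling act on the latent innovations through a
  Kronecker correlation: exchangeable 2×2 couple block (default
  `dyad_rho` = 0.3) ⊗ AR(1) over the three assessments (default
  `time_rho` = 0.5).  These defaults are ordinary magnitudes for
  within-family and month-scale retest correlations of distress scores.
- Latents are mapped affinely from ±3 SD onto the score range, rounded
  and clamped.  Round-and-clamp is transparent and monotone but is a
  fidelity limitation: real ordinal responses arise from threshold
  processes and show floor effects the generator does not model.
- The default design reproduces the attrition pattern of a paired
  longitudinal study: 23 enrolled couples, the last 7 fathers missing at
  t2/t3 (never t1), leaving 16 complete dyads.

The default planted networks use a symptom chain
(Anxiety–Depression–Somatisation–Hostility), a well-being chain, a
negative Anxiety–Relaxation bridge, an Anxiety–Depression coupling that
relaxes from 0.35 to 0.25 over time, and an extra mother-only
Anxiety–Somatisation edge.  These magnitudes are free parameters of the
simulation — they are *not* estimates of any real cohort, whose effect
sizes are unknown.

What passing tests on these cohorts shows: the estimator recovers planted
conditional-dependence structure at adequate n and controls false edges
under the null.  What they do not show: behavior under ordinal threshold
effects, non-Gaussian tails, informative dropout, or model
misspecification — none of which the generator produces.

## Classical statistics

- **K-S normality**: one-sample test against a normal reference; by
  default the reference mean/SD are estimated from the sample, which
  makes the asymptotic p-value conservative (the Lilliefors situation).
  A fixed reference can be supplied, in which case p is exact and the
  test is calibrated (verified by simulation).
- **Repeated-measures ANOVA**: one-way within-subject decomposition,
  F = MS_time / MS_(time×subject), df = (t−1, (t−1)(n−1)); no sphericity
  correction by default (a Greenhouse–Geisser epsilon is available
  separately).  Type-I error at α = 0.05 is verified to lie in
  [0.03, 0.07] under a null simulation at the study scale (n = 16).
- **Tukey HSD** from summary statistics, p-values from the studentized
  range distribution.
- **Power analysis**: the minimal detectable correlation solves
  power(r) = target, where power uses the Fisher-z approximation with
  bias correction atanh(r) + r/(2(n−1)), SE 1/√(n−3), and a rejection
  region from the t-based critical correlation.  At n = 16, α = 0.05
  two-sided, power = 0.8 this yields r ≈ 0.640.  Inversion tolerance
  1e−6; the returned value is verified by Monte-Carlo simulation of the
  exact t-test.  Published power routines differ in these approximation
  details at the ±0.01 level, which is why the acceptance band on this
  quantity is ±0.02.
- **Norm comparison** classifies a sample mean against the control mean
  ± 1 SD band; the shipped Anxiety norm is 4.25 ± 3.53.

## Mixed graphical model estimation

Nodewise penalized regressions on z-scored predictors: Gaussian lasso for
continuous nodes (z-scored response), L1 logistic regression for the
dichotomous node (unpenalized intercept).  Per node:

- λ grid: 50 log-spaced values from λ_max (smallest penalty zeroing all
  coefficients) down to 10⁻³ λ_max.
- 10-fold cross-validation with seeded random fold assignment; held-out
  loss is squared error (continuous) or logistic deviance (categorical);
  the grid minimizer is selected — no one-standard-error rule.
- **Post-CV threshold**: coefficients with |β| < τ = √(log p / n) are set
  to zero (`threshold_scale` rescales τ; 0 disables).  CV-minimum lasso
  alone admits many small spurious coefficients — measured here as ~2.8
  spurious AND-rule edges per 9-node null network at n = 200 — and the
  threshold is the standard remedy in nodewise MGM software.  With it,
  null networks average ≈ 0.7 spurious edges and planted chains at
  partial correlation 0.3 are recovered with sensitivity ≈ 1.0 and false
  edge rate ≈ 0.02 at n = 500.
- **AND rule** (default): an edge requires nonzero coefficients in both
  directions; OR is available.  Weight = mean of the two absolute
  standardized coefficients.  Continuous–continuous edges carry the
  shared sign; conflicting signs drop the edge onto a logged list.
  Edges at the categorical node are unsigned magnitudes (their weight is
  retained for path computations).
- Constant columns isolate their node with a warning.  Edge weights are
  reported on the standardized scale throughout; whether to standardize
  is not identified by the analysis being mirrored, and the standardized
  convention makes weights comparable across strata.

The inner solvers are numba-compiled coordinate descent (Gaussian: Gram
form; logistic: IRLS-curvature updates with step cap and a divergence
guard for separable data, where the small-penalty solution is unbounded).
They are verified against scikit-learn's `lasso_path` and saga logistic
solver to ~1e−6 in the test suite.

**Predictability**: continuous nodes report in-sample R² of an
unpenalized refit on the selected support (clamped to [0, 1]; isolated
node → 0).  The categorical node reports CC (in-sample accuracy of an
unpenalized logistic refit), CCmarg (majority-class accuracy) and
nCC = (CC − CCmarg)/(1 − CCmarg), floored at 0.

## Centrality and bootstrap

Strength is Σ_j |w_ij| (unweighted degree is emitted alongside, since the
verbal "number of connections" description of strength is ambiguous for
weighted graphs).  Betweenness uses edge length 1/|w| (Opsahl α = 1, not
exposed), Dijkstra geodesics, Brandes fractional counting of ties, raw
and normalized (÷ (p−1)(p−2)/2) variants.  Scale invariance (weights × c)
and equivalence to exhaustive path enumeration on ≤ 7-node graphs are
asserted in tests.

Stability uses a nonparametric case-resampling bootstrap (default
B = 1000 standalone, B = 200 in the pipeline default): each replicate
resamples stratum rows with replacement and re-estimates the full network
and both indices.  Summaries: bootstrap mean, percentile 2.5/97.5
interval (widened, rarely, to bracket the mean — heavy-tailed betweenness
distributions at small B can put the mean past the upper percentile),
and rank stability (share of replicates preserving the node's original
rank).  Replicate estimation failures are skipped and counted.  Per-edge
bootstrap inclusion proportions are recorded; edges with support < 0.5
are exported as "not significant" (rendered gray), since no sharper
criterion is identified for this design.

## Community structure and layout

Walk-trap community detection (igraph implementation, walk length t = 4,
the algorithm's usual default) runs on absolute weights; every dendrogram
level is re-scored with Newman weighted modularity
Q = Σ_c (e_c/m − (d_c/2m)²) on |W| and the maximum-modularity level is
chosen, so the chosen partition's Q is by construction ≥ every other
level's.  Edgeless graphs yield singletons.  Block-recovery tests use
stochastic block models conditioned on each planted block being
internally connected — a realization in which a block member has no
within-block edge does not instantiate the planted structure and no
algorithm could recover it.

Layouts: Fruchterman–Reingold (networkx spring implementation, 500
iterations, seeded), min–max rescaled to the unit square (degenerate axes
map to 0.5).  For cross-stratum comparability one **average layout** is
computed from the element-wise mean of the absolute weight matrices and
reused unchanged for every network.  Node sizes are
1 + (mean_Tk − mean_T1)/mean_T1 per subscale, floored at 0.2; signs color
edges green (positive) / red (negative) only — they never affect walks or
layout.

## Pipeline and reproducibility

A single global seed derives per-stage seeds via
`SeedSequence([seed, stage_index])`, all recorded in the run report;
identical configurations produce byte-identical reports, cohort CSVs,
layouts and bootstrap summaries.  The JSON and markdown report forms are
generated from the same dictionary.  The default full run (23 dyads,
B = 200 bootstrap over six strata) takes ≈ 2½ minutes on one CPU; tests
use smaller B and stratum sizes chosen to keep the suite around a minute
while still exercising every stage.

## Known limitations

- Round-and-clamp discretization, not threshold-based ordinal responses.
- Dropout is fixed by design (father indices at t2/t3), not stochastic or
  informative.
- In-sample predictability overstates out-of-sample predictive accuracy
  at n = 16.
- The walk-length and layout parameters are conventions; reported
  cluster counts and coordinates are convention-dependent.
- No k ≥ 3 interactions, time-varying networks, or multilevel (couple)
  random effects in the estimator itself.
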