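# Methods

This note records the statistical model behind `crss`, the choices made
where the design was genuinely open, and what the synthetic cohorts do and
do not establish.

## Cohort model and preprocessing

A cohort is a table of NDMM patients with six continuous prognostic
parameters (age in years; albumin g/dl; β2M mg/L; calcium mg/dl; eGFR
ml/min/1.73 m²; hemoglobin g/dl), an optional LDH measurement with its
assay's upper limit of normal (ULN), a pooled binary HRCA flag, and two
right-censored endpoints in weeks (PFS and OS, events coded 0/1).

* **eGFR** is derived from serum creatinine when absent, using the
  IDMS-traceable 4-variable MDRD equation
  `175 · SCr^-1.154 · age^-0.203 · 0.742[female] · 1.212[black]`.
  The 175-coefficient form is the contemporary standard; a supplied eGFR
  always wins over creatinine, and a row with neither is rejected.
* **LDH** values from different assays are mapped to a common scale by
  `ldh · 280 / uln`, so a measurement at its ULN becomes 280 U/L; "high
  LDH" then means > 280 on the common scale.
* **Missing values** of the continuous parameters are imputed with the
  column median of the observed values (idempotent by construction); no
  multiple imputation is attempted. Patients without HRCA assessment are
  retained for cutoff discovery but excluded from model building, mirroring
  the typical situation where cytogenetics cover only part of a registry.
* **Dichotomization** follows fixed per-parameter directions: age is high
  risk strictly above its threshold; β2M and calcium at or above; albumin,
  eGFR and hemoglobin at or below. Thresholds typeset with ≥/≤ are
  inclusive, with > exclusive, and the boundary semantics are honored
  exactly.
* **ISS / R-ISS** staging is provided as the benchmarking baseline:
  ISS I = β2M < 3.5 and albumin ≥ 3.5, ISS III = β2M ≥ 5.5, else II;
  R-ISS I = ISS I without HRCA or high LDH, R-ISS III = ISS III with HRCA
  or high LDH, else II. Patients lacking HRCA or LDH are simply excluded
  from R-ISS comparisons.

## Survival primitives

Kaplan–Meier estimation and the two-sample log-rank test are implemented
directly on numpy arrays (standard tie handling; the log-rank variance term
uses the hypergeometric form with the (n−d)/(n−1) correction). This keeps
the cutoff search cheap — several hundred log-rank evaluations per
parameter cost milliseconds — and both primitives are cross-checked against
lifelines in the test suite. Cox proportional-hazards fits delegate to
lifelines' `CoxPHFitter` with Efron tie handling (the only method lifelines
implements; ties are rare-to-absent in the week-scale data the package
targets). Reported per-fit quantities: coefficients, hazard ratios with
Wald 95% confidence intervals and p-values, the log partial likelihood,
Harrell's concordance (pairs with a censored earlier time excluded, tied
scores counted ½), `AIC = −2·logPL + 2k` and `BIC = −2·logPL + k·ln(d)`
with d the number of events. Yearly survival summaries convert at
52.18 weeks per year and read the right-continuous step function; the
median is the first time S(t) ≤ 0.5 and is flagged, not erred, when never
reached. Stage-wise distributional comparisons use Kruskal–Wallis plus
successive pairwise Wilcoxon rank-sum tests.

## Cutoff discovery

The search space for a parameter is the set of midpoints between
consecutive distinct observed values whose induced split leaves at least
`min_fraction` (default 0.1) of the cohort on each side. The search is
exhaustive — cohorts of a few thousand make pruning pointless — and keeps
the threshold maximizing the log-rank chi-square, breaking ties toward the
smaller threshold. Run once per endpoint, the PFS and OS candidates are
reconciled by absolute distance to the established clinical cutoff (ties to
the smaller threshold). Two deliberate simplifications: the number of
subgroups is fixed at two (the system only ever consumes one cutoff per
parameter), and **no multiplicity correction is applied to the selected
cutoff's p-value**. The latter matters: a maximally selected log-rank
statistic is optimistically biased, and with a grid spanning the 10–90%
quantiles roughly half of truly null markers will show a naive p < 0.05
(Miller–Siegmund). The p-values attached to proposed cutoffs are therefore
descriptive summaries of separation, not evidence against a null; any
confirmatory claim needs an independent cohort.

## Consensus staging

Three weight tables are derived on the model-building subset (HRCA known,
parameters imputed):

* **multivariate rank** — all seven dichotomized flags enter one Cox fit on
  a single endpoint (default OS, configurable; the choice of endpoint for
  this scheme is genuinely open and documented rather than hidden); the
  parameters are ranked 1..7 by ascending hazard ratio, exact ties broken
  by name order, so the weights are always a permutation of 1..7.
* **univariate hazard ratio** — per parameter, the larger of the PFS and OS
  univariate hazard ratios, min-max scaled to [0, 1]; an all-equal
  degenerate table collapses to all-ones.
* **p-value** — per parameter, the smaller of the PFS and OS log-rank
  p-values, passed through −log₁₀ before min-max scaling so that stronger
  evidence yields a larger weight. A literal min-max of the raw p-values
  (which would give the most significant parameter weight 0, inverting the
  intended meaning) is retained behind `pvalue_mode="literal_minmax"` for
  fidelity experiments only. Exact zeros are clamped to 1e-300 with a
  warning.

Each table turns a patient's flags into a weighted burden score; each score
vector yields the adjacency graph of pairwise absolute differences. The
rows of each graph are clustered with a 3-component Gaussian mixture —
diagonal covariances with a 1e-6 variance floor (rows of an n×n matrix make
full covariances singular), 10 seeded restarts keeping the best likelihood,
so labels are a deterministic function of the seed. Three components match
the three target stages. The consensus graph counts co-assignments over the
three labelings (entries 0–3, zero diagonal, invariant to relabeling);
average-linkage agglomerative clustering on the distance 3 − consensus cuts
it into three clusters, which are ordered into stages by ascending mean
rank-scheme score (ties toward the smaller cluster id). An all-zero
consensus still yields three clusters, with a degeneracy warning.

All component seeds derive deterministically from one pipeline seed via a
`SeedSequence`, so an identical cohort, configuration and seed reproduce
the stage assignment and the serialized model byte for byte.

## Rule distillation and prediction

The consensus stages supervise a CART tree (Gini impurity, default depth 4,
minimum leaf 5, seeded) over the **raw** parameter values plus the binary
HRCA flag — raw rather than dichotomized inputs, because the interesting
output is where the tree chooses to split, which need not coincide with the
scoring cutoffs. Root-to-leaf paths become an explicit rule list (mutually
exclusive and exhaustive by construction; rule thresholds are exactly the
split thresholds; leaf class proportions are kept as probabilities). The
tree's training fidelity to the consensus labels is recorded on the rule
set. Deployment uses the rules alone: the stage of a new patient is the
verdict of the unique matching rule, and the staged cohort written by
`train` likewise carries the rules' verdicts (the consensus labels exist
only to supervise the tree). A single JSON artifact bundles cutoffs, weight
tables, rules, seed and configuration.

## Shapley explanations

For one patient and one stage, the class-probability output of the rule set
is a cooperative game over the k = 7 features. Coalition values are
interventional: v(S) is the mean predicted probability over a background
cohort (default: the training cohort) with the features in S overwritten by
the patient's values. Contributions use the exact Shapley formula over all
2⁷ = 128 coalitions, which makes the efficiency identity
`base + Σφ = f(patient)` hold to ~1e-15 and provides its own oracle (the
test suite confirms equality with averaging over all 7! orderings).
Path-dependent (tree-traversal) expectations were deliberately not used:
with seven features exact interventional enumeration is cheap and has
cleaner axioms. Beyond 15 features the implementation refuses and points to
sampling; no sampling mode is shipped because the clinical models here
never need it.

## Synthetic cohorts

The generator produces the structure the pipeline assumes, not a facsimile
of any real registry:

* Each patient draws a latent stratum (low / intermediate / high,
  equiprobable). Under the default **burden** flag model the stratum fixes
  how many of the six parameters are flagged high-risk — k·q_s randomized
  to the two bracketing integers, with the preset separation of 1.0 giving
  exact bands 0 / 3 / 6 — and the flagged subset is uniform. Exchangeable
  subsets mean every parameter's within-stratum flag probability is exactly
  q_s, so the pooled flag fraction equals the fraction implied by the
  marginal, and values drawn from the side-truncated marginal reassemble
  the configured distribution exactly. An **independent** per-parameter
  flag model is available for less stylized cohorts; it was not made the
  default because with estimated min-max/rank weights the resulting score
  overlap makes the three strata unidentifiable in principle, not just in
  practice.
* Preset marginals (normal or lognormal, clinical units) place each planted
  cutoff at the distribution median — the shared-quantile constraint the
  burden model needs — with spreads chosen to keep ranges clinically
  plausible: e.g. `mmin_like` uses age ~ N(67, 11), hemoglobin
  ~ N(12.3, 2.1), β2M ~ logN(ln 4.78, 0.55). HRCA prevalence is
  stratum-graded (5% / 35% / 70%).
* Survival is exponential proportional hazards: each flag multiplies the
  baseline hazard by exp(effect), with equal effects ln 1.4 for the six
  laboratory parameters and ln 1.25 for HRCA — equal by design so the
  multi-parameter burden, not a single marker, drives prognosis. Death and
  progression share the multiplier (baselines 0.0015 and 0.001 per week),
  PFS = min(progression, death) so PFS ≤ OS per patient, censoring is
  independent exponential (0.0015/week) with an 11-year administrative cap.
  At the defaults this yields ~70–80% event rates and cohort median OS
  around 110–170 weeks, in the range typical of NDMM registries.
* Optional missingness injection (continuous parameters except age and
  eGFR, and/or the HRCA flag) exercises imputation and the
  HRCA-known/unknown split.

What passing tests on these cohorts show: the pipeline recovers planted
cutoffs, separates planted strata (adjusted Rand index ≥ 0.95 across seeds
at n = 400), produces monotone stage-wise hazard ratios, and distills
faithful rules. What they do not show: performance under correlated
real-world parameter distributions, treatment effects, informative
censoring, or strata that are not burden-banded — on real registries the
stage boundaries and discrimination must be re-validated.

## Numerical and operational choices

* Log-rank returns chi-square 0 (p = 1) when the variance is zero (no
  events, or one group exhausted).
* Identical samples short-circuit the rank tests to p = 1 rather than
  erroring on zero variance.
* Cutoff grids use midpoints, so group sizes never depend on boundary
  inclusion; grid ties always resolve to the smaller threshold.
* Stage models, cutoff tables and rule sets serialize to sorted-key JSON;
  determinism is asserted at the byte level in the tests.
* The CLI writes a run log (options, seed, library versions, SHA-256 input
  hashes) next to every primary output.

## Known limitations

* Only two-group cutpoints and exactly three stages; no soft stage
  membership.
* Selected-cutoff p-values are not selection-adjusted (see above).
* Efron is the only Cox tie-handling method available.
* The Shapley implementation is exact-only (≤ 15 features).
* The synthetic generator does not emulate cross-parameter correlation
  beyond the shared stratum, nor treatment arms.
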