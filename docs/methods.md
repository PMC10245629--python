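# Methods

## Study design being implemented

The package implements a retrospective matched cohort design for
evaluating the cost-effectiveness of polymyxin B hemoperfusion (PMX) in
septic shock, as applied to nationwide inpatient administrative claims.
All days are 1-based with day 1 = the day of sepsis diagnosis,
operationalized as the first recorded SOFA score. The treated arm is
patients whose first PMX session fell on day 1 or 2; patients first
treated later are excluded outright (they belong cleanly to neither arm),
and untreated patients form the control pool.

Eligibility: age ≥ 20; baseline SOFA in [7, 12] (the range where the
treatment's clinical benefit has been observed); no death within 3 days of
diagnosis; stay ≤ 125 days; no transfer-without-recovery by day 28. The
filters are pure row predicates, so the surviving set is order-invariant;
the attrition report lists them in the conventional flow order.

## Propensity model and matching

The propensity score is a maximum-likelihood logistic regression of
treatment on 17 baseline covariates (age, sex, emergency admission,
university hospital, ER/ICU admission, Charlson index, CRRT, hemodialysis,
mechanical ventilation, surgery, γ-globulin, antithrombin III, recombinant
thrombomodulin, steroid, RBC and platelet transfusion, maximum daily
noradrenaline dose). Baseline SOFA is deliberately **not** in the model —
the eligibility window already restricts it to 7–12 — which leaves a small
channel of residual confounding that the matched estimator cannot remove;
the debiasing test quantifies that this channel is minor relative to the
confounding the matching does remove.

Matching is greedy 1:k (default k = 3) nearest-neighbor without
replacement. The caliper is 0.2 × SD of the score over the full pre-match
eligible sample, on the probability scale by default (a `logit` scale
option is provided, as that is common practice). Treated patients are
processed in a seeded random permutation of their sorted ids — the order is
part of the reproducibility contract — and each takes its k nearest unused
in-caliper controls, breaking exact distance ties by smaller id. A treated
patient with fewer than k available in-caliper controls is dropped and
reserves nothing; this "complete sets only" rule keeps the matched design
exactly 1:k. The `MatchedCohort` object re-validates completeness, control
non-reuse and the caliper bound at construction, so every run is checked.

Note that "a wider caliper never matches fewer treated patients" is a
statistical regularity of this algorithm on realistically dense control
reservoirs, not a theorem: in sparse adversarial configurations a treated
patient rescued by a wider caliper can consume controls that two later
treated patients each needed. The test suite asserts the monotone behavior
on seeded dense instances only.

Balance is reported as the absolute standardized difference in percent:
`100·|m̄_t − m̄_c| / sqrt((s²_t + s²_c)/2)` with sample variances for
continuous covariates and `p(1−p)` variances for binary ones; a covariate
with zero pooled variance but differing means reports +∞ with a warning.

## Outcomes

Free days at day 28 count days in [1, 28] alive and free of the given
support; days after a live discharge count as free. A death strictly
before day 28 zeroes all free days. A death exactly **on** day 28 counts
as a 28-day death yet still accrues free days under the default
convention (a literal reading of "died before day 28"); the stricter
convention is available via `death_on_day_28_zeroes=True`. Mortality
contrasts use the Pearson χ² statistic without continuity correction
(via `scipy.stats.chi2_contingency`); a degenerate table (e.g. no deaths
in either arm) reports a NaN p-value rather than failing. Rank-based
contrasts use the two-sided Wilcoxon rank-sum test: the exact permutation
distribution for ≤ 20 observations per arm without ties, a full
enumeration over midrank assignments for small tied samples (bounded at
~4·10⁵ assignments), and the tie-corrected normal approximation otherwise.
Medians and IQRs use linear interpolation between order statistics
(`numpy.percentile` default) — a convention had to be fixed and this is
the most common one.

## Life table and the value of survival

Residual life expectancy comes from a CSV life table (`age, sex,
life_expectancy`); abridged 5-year tables are interpolated linearly to
single years, ages above the oldest knot use the oldest knot's value
(floor extrapolation, never negative), and a "total" query against a
male/female-only table takes the unweighted sex mean. Lookup uses the
"total" stratum by default — the study design computes expectancy from age
alone — with a `by_sex` option for the realistic variant. The packaged
fixture table is synthetic (≈63 years remaining at age 20, declining
smoothly to ≈1.5 at 110, ~3-year female advantage); it exists so the
pipeline runs without external data and is *not* any official national
table, so absolute LE/QALY levels from synthetic runs are not comparable
to the published ones.

Patients who die in hospital contribute LE = 0 — they have no life after
discharge — which is the only reading under which arm-mean life
expectancies can differ through mortality, as the published arm means do.
Survivors' LE is looked up at the recorded age (admission age; stays are
short relative to a year). The chain LYG = LE·r, QALY = LYG·u is linear,
so arm-mean QALY = r·u·arm-mean LE exactly, and the QALY difference used
in the ICER denominator is r·u·ΔLE. Defaults r = 0.51 (excess post-sepsis
mortality) and u = 0.69 (post-sepsis utility); both come from older
literature and are therefore varied over {(0.3, 0.6), (0.7, 0.8)} in the
sensitivity analysis. No discounting of future life years or costs is
applied (none was in the source design); costs convert at 130 JPY/EUR.
The ICER denominator is the QALY difference (the displayed formula), not
the life-expectancy difference mentioned in passing prose. The
willingness-to-pay threshold is 38,462 EUR/QALY (5 million JPY/QALY);
`wtp_decision` classifies dominance (cheaper-and-better /
costlier-and-worse) when the signed deltas are supplied.

Subgroup analyses stratify the *already matched* cohort by each patient's
own SOFA band (7–9 vs 10–12) and infection site (abdominal vs other);
matched sets may straddle strata, so stratum arms need not be 1:3.

## Synthetic cohort generator

The generator emulates the published unmatched cohort: covariate marginals
target the published control-arm values (age 77.2 ± 12.7; male 55%; CRRT
10.8%; mechanical ventilation 21.9%; maximum noradrenaline 7.4 ± 9.9;
etc.), treatment prevalence targets 7.7%, and baseline (untreated)
hospital mortality targets 32%.

Design choices, made once:

- **Dependence chain.** Baseline SOFA is drawn from a discretized normal
  (mean 9.5, SD 2.5, support 2–17 — wide enough that the SOFA filter has
  work to do). CRRT and ventilation probabilities and the noradrenaline
  scale rise with SOFA (log-odds slopes 0.35/0.30, log-scale slope 0.10);
  their intercepts are solved exactly against the SOFA pmf so configured
  marginals are recovered in expectation. Independent covariates would
  make matching trivially easy; full joint realism is impossible since
  only marginals were published.
- **Assignment model.** Treatment is logistic in the 17 matching
  covariates with signs mirroring the published treated-arm shifts
  (strongly positive on CRRT, ventilation, surgery, adjunct drugs,
  transfusions, noradrenaline; negative on age, male sex, emergency
  admission). The intercept is solved on a fixed-internal-seed covariate
  sample of 60,000 so the marginal treated fraction hits its target; that
  calibration is deterministic and independent of the user's seed.
- **Outcome model.** Death is logistic in SOFA, age, CRRT, ventilation and
  noradrenaline plus the true treatment effect, default log(0.625) ≈
  −0.47 (the odds ratio implied by the published matched mortality rates,
  24.4% vs 34.1%). Death day ~ round-lognormal(median 12 d, σ 0.85) —
  putting mass on days ≤ 3 so the early-death filter is exercised — with
  stay = death day for decedents; survivor stays ~ round-lognormal(median
  24 d, σ 0.65, ~1% above 125 d so the long-stay filter is exercised) with
  a +0.18 log shift for treated patients (longer stays among survivors).
  4% of survivors transfer without recovery. ~8% of PMX starts fall on
  day 3–4 so the late-treatment filter is exercised.
- **Costs.** Each of the 11 claims categories is an independent gamma draw
  matching the published control-arm mean and SD (in EUR, stored in JPY at
  130), identical across arms except for an additive device cost of
  4,461 EUR on the "treatment" category for treated patients — the
  dominant published cost-difference channel. Costs are *not* linked to
  stay length or mortality; between-arm differences in the other
  categories are therefore ≈ 0 in expectation, unlike the real data where
  longer treated stays inflate hospitalization costs.

What passing tests therefore show — and what they do not: the pipeline
recovers configured marginals, removes induced confounding (all 17
post-matching ASDs < 10% at n = 20,000; matched mortality log-OR closer to
truth than the crude one in ≥ 90% of 50 seeded replicates at n = 8,000 per
replicate, a size chosen to keep matched-estimator noise well below the
confounding bias), and reproduces the published deterministic arithmetic
exactly. They do not show that the real cohort's absolute levels (matched
n, LE means, cost SDs) would be reproduced; those depend on the real joint
covariate distribution and the authors' life table, neither of which is
public.

## Numerical conventions and degenerate inputs

- Propensity fit: Newton/IRLS via statsmodels; a singular Hessian (e.g. a
  constant covariate) falls back to BFGS, leaving unidentified slopes at
  zero; perfect separation raises a dedicated error rather than returning
  divergent coefficients.
- ICER with ΔQALY = 0 raises an undefined-ICER error (0/0 returns 0);
  empty stratum arms raise in the base analysis and skip-with-warning in
  the subgroup loop.
- Caliper comparisons tolerate 1e-12 float slack; match-order ties break
  by smaller id.
- Generated tables are deterministic functions of the config (single
  `numpy.random.default_rng(seed)` stream); the matching order is seeded
  separately so the same cohort can be re-matched reproducibly.
- Currency is displayed as integer EUR and years to 2 decimals; all
  internal arithmetic is full precision. (The published base-case ratio
  6935/(1.70·0.51·0.69) = 11,592.53 actually rounds to 11,593 where the
  source table prints 11,592 — the recomputation agrees within the 1
  EUR/year slack that rounding of the printed inputs already implies.)

## Known limitations

- The generator's joint covariate structure is a modeling choice; only
  marginals are anchored to published values.
- Residual confounding through baseline SOFA (excluded from the
  propensity model by design) is present in the synthetic data, as it
  plausibly is in the real analysis.
- The exact vintage and sex stratification of the life table behind the
  published LE levels (12.93 / 11.23 years) is unknown; only the
  downstream arithmetic is reproducible, and the package checks exactly
  that.
- Whether the original nearest-neighbor matching was greedy and in what
  order is unstated; exact reproduction of the published matched set is
  impossible without the source data, so the greedy/seeded-order contract
  here is the package's own, verified against its brute-force oracle.
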