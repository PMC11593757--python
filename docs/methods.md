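# Methods

## Scope and data model

`careband` estimates how far observed monthly measurement rates of 12
cardiometabolic risk-factor clusters (BMI, smoking, alcohol, BP, HbA1c,
fasting glucose, total/LDL/HDL cholesterol, triglycerides, LFT, eGFR)
deviate from a counterfactual expectation after March 2020. Inputs are a
person table (age at the November 2018 index, sex, ethnicity, IMD
quintile, death month, months of follow-up) and a record-level event table
(person, calendar day, factor, optional value), either synthetic or
supplied. All months are calendar months; the study window is November
2018 – March 2024.

## Curation

Persons are excluded in a fixed cascade — under 18 at index, unknown sex,
no valid residential area (modelled as a missing IMD quintile), under one
month of follow-up — with each person attributed to the first failing
rule, so the tally partitions the input exactly. Records are then
filtered: at most one record per (person, factor, day), keeping the first
in input order; records without a value are dropped except for smoking and
alcohol, which are meaningful as coded observations alone. The two filters
commute whenever same-day same-factor records agree on value-missingness
(the generator guarantees this for its injected duplicates); the pipeline
fixes the order dedup → value filter.

Monthly rates are `count / denominator × 1000`, where the denominator for
month *m* counts eligible persons whose follow-up covers any part of *m*;
a person who dies contributes through their death month. This
whole-month convention was chosen over person-days because censoring is
recorded at month resolution; it slightly overstates denominators in death
months (negligible at the death rates involved). A zero denominator in any
reported month is an error, not a silent NaN. Counts published for
disclosure are rounded to multiples of 5 (ties away from zero) strictly at
output time, never before modelling.

## Trend model

For one factor, counts per stratum-month follow a quasi-Poisson log-link
model with offset `log N`:

* categorical main effects for any stratification dimensions (treatment
  coding, first level as reference);
* a cyclic P-spline over month-of-year: `k = 6` cubic B-spline basis
  functions on equally spaced knots wrapped on a period of 12, with a
  second-order cyclically wrapped difference penalty. Six basis functions
  are deliberately parsimonious because the default fit window holds only
  16 months; `k` is configurable.
* a linear trend in `t` = years since March 2020 (exact month offsets
  divided by 12), plus `t` × category interactions.

Identifiability: a periodic B-spline basis sums to one everywhere, so the
seasonal block is collinear with the intercept. The basis is therefore
reparameterized onto the null space of its column-mean vector (a
sum-to-zero constraint, as in mgcv), leaving `k − 1` seasonal columns; the
penalty is transformed congruently. Remaining rank deficiency in the
design raises an explicit error.

Fitting is penalized IRLS with Poisson working weights, converging when
the relative deviance change drops below 1e-8 (cap 100 iterations;
non-convergence is reported, never hidden). The dispersion is
`φ = Pearson χ² / (n − edf)` with `edf = tr[(XᵀWX + λS)⁻¹XᵀWX]`, and the
coefficient covariance is `φ(XᵀWX + λS)⁻¹`. The smoothing parameter is the
minimizer of `GCV(λ) = n·χ²/(n − edf)²` over a log-spaced grid
(10⁻²…10⁴ by default), ties broken toward the smoother fit. All intervals
are Wald with the normal quantile 1.959964. The standard offset contract
holds: shifting the offset by a constant moves only the intercept.

One joint model per factor is fitted across all strata (matching the
stated interaction structure) rather than one model per stratum; the
stratified alternative can be had by filtering the rate table first.

## Expectation bands and deviations

Expected rates after March 2020 come from two projections of the fitted
model: *continued trend* (use each month's true `t`) and *frozen trend*
(clamp `t` at 0 for months after March 2020, leaving earlier months
untouched). Each yields `rate = 1000·exp(η)` with a 95% CI
`1000·exp(η ± z·se)`. The composite band takes the union — minimum of the
lower bounds, maximum of the upper bounds — and its midpoint is the point
estimate of the expected level. The band therefore always contains both
component intervals, and widening either component can only widen it.

Deviations: absolute `O − E` with interval `(O − U, O − L)`; relative
`100(O − E)/E` with endpoints evaluated at `E = U` and `E = L`
respectively (each deviation bound uses the matching band edge; the paper
trail of printed tables shows such intervals are computed on unrounded
values, which is what the code does). Period summaries average the monthly
observed rate and the monthly band bounds over the period's months, then
apply the same formulas; summing to period totals instead of averaging was
considered and dropped — means keep the per-1,000-per-month scale of the
monthly series. "Overall" series can be produced either by fitting an
unstratified model or by count-space aggregation of stratum expectations
(expected counts summed, divided by the summed denominators); aggregation
is the default because it preserves the stratified model's fit.

A structural property worth knowing: the band midpoint is the average of
two *exponentiated* interval edges, so when `se(η)` is large (small
cohorts, long extrapolation) the midpoint sits above the geometric centre
of the projections, and when the true trend is non-zero the midpoint
deliberately splits the continued and frozen counterfactuals. Both effects
make long-horizon point deviations conservative (biased away from zero) at
synthetic desk scales; with national-scale counts the intervals are tiny
and the midpoint collapses onto the projections. This is why the
calibration bench assesses recovery of an injected disruption in the first
summary period, closest to the fit window.

## Synthetic generator

Counts per person-month-factor are drawn with mean

```
μ = exp(base_f + effect_g + A_f·cos(2π(pos(m) − phase_f)/12) + β_year·t + log g_f(m))
```

and variance `φμ` via a Poisson-gamma mixture (negative binomial matched
to the first two moments — the analysis model only asserts quasi-Poisson
variance, and the NB mixture is the standard generative law with those
moments). `g_f` is a multiplicative disruption profile: 1 before onset, a
step drop to `depth` at onset, exponential return with half-life `h`
months toward `1 + post_offset` (infinite `h` holds the drop constant).
Subgroup structure is four independent marginals (age band, sex,
ethnicity, IMD) with additive log-rate effects; the defaults mirror a
large adult primary-care population (41.6/32.4/21.0/5.0% age bands,
50.3% female, 77.7% White, near-uniform IMD) and a BP baseline of 0.115
measurements per person-month (≈115 per 1,000 per month). Events carry a
uniform day within the month (needed for same-day dedup); duplicates are
appended at `dup_prob` copying the original's content; values are blanked
at `valueless_prob`; contaminants (under-18s ~25%, unknown sex, missing
IMD, zero follow-up) are injected per person; deaths follow a monthly
geometric hazard by age band. Seasonality is a single cosine *on purpose*:
the spline fit is thereby tested against a mildly misspecified truth.

What the generator does **not** emulate: SNOMED code clusters, GP
registration churn or deregistration, within-person event clustering
beyond NB overdispersion, correlated subgroup mixes, or national-scale
magnitudes. Passing tests therefore demonstrate correctness of the
pipeline's arithmetic and calibration under the stated generative law, not
fidelity to any real population.

## Calibration benches and problem sizes

Two bench scenarios (single BP-like factor, 40,000 persons of whom
~30,000 survive the exclusion cascade, φ = 1.5, amplitude 0.10) are run
for 200 replicates each:

* **null**: annual trend −0.02/yr, no disruption — checks how often
  observed post-onset monthly rates fall inside the composite band;
* **sustained disruption**: zero trend, depth 0.8 held from March 2020 —
  checks that the restrictions-period relative deviation recovers −20%.
  Zero trend is used so the two counterfactuals coincide in expectation
  and the band midpoint targets the undisrupted level.

The unit suite runs smaller versions (hundreds to a few thousand persons,
60 replicates for slope-coverage) so the default `pytest` run stays within
a few minutes; the bench sizes are stated here as the package's chosen
operating points. Observed-rate coverage of the band is *not* nominal by
construction: the band is a confidence region for the expected level, not
a prediction interval, and trend-estimation error is common to every
projected month of a replicate, so per-replicate coverage is strongly
clustered (measured pooled coverage is around 90% at these scales, with
occasional replicates far below).

## Numerical conventions and limitations

* Reporting rounding is half-away-from-zero (1 decimal for rates and
  deviations, 2 for the trend index); internal computation is never
  rounded.
* Reproducibility: every stochastic routine derives its stream from the
  scenario seed; identical configurations give byte-identical tables.
* The PIRLS initialisation is `μ₀ = y + 0.5`; degenerate all-zero strata
  warn and flag rather than fail.
* No REML smoothing selection, tensor-product smooths, autocorrelation
  modelling, or person-level repeated-measures structure.
* The exponential-recovery disruption profile is a modelling convenience;
  real post-pandemic recovery shapes are irregular.
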