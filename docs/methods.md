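# Methods

## Outcome model and the variance from categorisation

The gold-standard outcome is an integer rating scale `lo..hi` (default
0–99, "100 levels"). An M-category measure partitions those integers into
ordered categories and assigns every participant the category's midpoint
value ȳ_m. The variance from outcome categorisation is the pmf-weighted
mean squared assignment error; with one category (everyone assigned the
scale midpoint, 49.5 by default) it is the variance of non-measurement. All
interval logic is closed on integer endpoints.

**Scale layouts.** The canonical 0–99 layouts were historically constructed
by hand and do not follow a single formula, so `make_scale` carries them
explicitly under the default `"published"` convention:

| M | category blocks | midpoints |
|---|---|---|
| 2 | 0–49, 50–99 | 24.75, 74.5 |
| 3 | 0–32, 33–65, 66–99 | 16.5, 49.5, 82.5 |
| 5 | five blocks of 20 | 9.5, 29.5, …, 89.5 |
| 8 | blocks cut at multiples of 12.5 | 6.25, 18.75, …, 93.75 |
| 10 | ten blocks of 10 | 4.5, 14.5, …, 94.5 |

Note the deliberate asymmetry of the dichotomy (24.75 = centre of the real
interval [0, 49.5], but 74.5 = centre of the integer block 50–99); the
symmetric alternative (24.5) changes the uniform-outcome variance from
208.28 to 208.25. `convention="mean"` switches every midpoint to the exact
centre of its integer block, which for a uniform population is the category
mean. For any other (lo, hi, M) combination the generic layout is
near-equal contiguous blocks — remainder integers going to the earliest
categories — with block-centre midpoints.

A 15-category layout consistent with the historically reported
uniform-outcome value (5.46) could not be reconstructed: every equal or
near-equal partition of 100 points into 15 categories gives ≈ 3.7. M = 15
therefore uses the generic layout, and its cells should not be compared
against that source value.

## Population distributions

Uniform: equal mass on each integer. Constrained discrete normal: a normal
with location μ (default 49.5) and scale σ is truncated at the scale
endpoints `[lo, hi]` and binned to the nearest integer (integer k receives
the truncated mass on [k−0.5, k+0.5]; edge bins are half-width), then
renormalised. This convention reproduces the classical non-measurement
variances to ≤ 0.03% across σ = 5…25 (25.08 ≈ 5² + 1/12 by Sheppard's
correction; 479.07 for σ = 25, where truncation at ±1.98σ bites hard).
Truncating half a unit *outside* the endpoints instead inflates the σ = 25
variance by ~1%, which is why the endpoint convention is the default; a
sample–round–renormalise generator (`sample_discretised_normal`) is
provided for sensitivity checks of the discretisation itself.

Known limitation: for wide distributions (σ ≥ 20) combined with fine scales
(M ≥ 5), historically reported categorisation variances exceed what any
in-range pmf with the published midpoints can produce (e.g. ≈ 20.5 for
M = 10, σ = 25 against an equal-bin ceiling of ≈ 8.6); those cells are not
reproducible under any convention we could construct and are excluded from
the package's validated surface.

## Sample size and the decision rule

Per-arm sample size uses the normal-approximation formula
n = F(σ₁² + σ₂²)/d², F = (z₁₋α/₂ + z_power)², equal arms, no t- or
continuity correction. `required_n` returns a real number; rounding is a
costing concern (`ceil=True`) so that the algebraic identity behind the
decision rule stays exact.

Measurement noise enters as effective variance. Default (`"classical"`)
model: a measure with concurrent validity r observes ŷ = y + e with error
variance σ²(1 − r²)/r², giving effective variance σ²/r² + σ_c². This makes
corr(ŷ, y) = r when categorisation is ignored. The alternative
(`"attenuation"`) mode shrinks the detectable effect, d → r·d, equivalent
to dividing the *whole* variance (σ² + σ_c²) by r²; the two differ only in
whether σ_c² is also scaled. Neither mode models differential (biased)
error — that risk is a qualitative screen, not a computation.

Because total measurement cost per design is 2·n·unit_cost ∝ effective
variance × unit cost, "cheap wins" ⇔ variance ratio < unit-cost ratio,
exactly. Ties resolve to the gold standard (lower information-bias risk).
Totals are computed from real n by default so this equivalence is exact;
ceiling is opt-in.

## Burden–response meta-regression

Per trial, the effect is the log odds ratio of response (long vs short
arm), variance the sum of reciprocal cell counts (Woolf); any zero cell
triggers a +0.5 Gart correction to all four cells. The model regresses log
OR on log length-ratio with weights 1/(v_i + τ²); τ² is estimated by
profiling the restricted (REML) log-likelihood with a bounded scalar
optimiser, checking the τ² = 0 boundary explicitly. Standard errors come
from the weighted information matrix and the 95% CI is z-based (± 1.96·se),
matching standard meta-analysis software; the implementation is verified
against `metafor::rma` in the test suite.

The pseudo-R² ("heterogeneity explained") is the proportional reduction in
τ² against the intercept-only REML model, floored at zero — one of several
conventions in use; it is reported, not interpreted further. A quadratic
term in log RQ is available as an explicit model variant (`quadratic=True`),
never auto-selected.

**Synthetic trial generator.** `synth_trials` emulates a corpus of
randomised long-vs-short questionnaire trials: log length-ratio uniform on
[log 1.25, log 4] (typical page-count ratios in such trials), an additive
study effect Normal(0, τ²) on the log-OR scale, short-arm response
probability 0.7 (typical of postal questionnaires), 200 participants per
arm, binomial counts. Defaults for the recovery study follow the reported
conditions: K = 40 trials, slope −0.594, τ = 0.25. `sampling="expected"`
emits expected (non-integral) counts — the noiseless limit used for
consistency checks. What the generator does *not* emulate: risk-of-bias
heterogeneity, mixed length units, publication bias, or correlation between
trial size and length ratio — so passing recovery tests validate the
estimator under the stated model, not robustness to those features of real
trial corpora.

## Cost-ratio simulation

Fully analytic per grid cell (no sampling, so output is byte-reproducible):
build the constrained normal for the cell's SD, take σ_c² for the scale,
form effective variances (gold: r = 1, σ_c² = 0), convert to per-arm n at
α = 0.05, power 0.9, d = 0.1, validity 0.7, costs £50 vs £5 — and price
both designs. Default SD grid 0.5–25 in steps of 0.5 (SD = 0 is a
degenerate outcome and is excluded); category counts {3, 5, 8, 10, 15}.

Non-response penalty: burden is proxied by item count (gold = 100 levels
counts as 100 items; an M-category questionnaire as M items — configurable,
since length units are genuinely arbitrary here). RQ is each measure's
length relative to the shortest measure in the scenario. The default
`response_model="rate"` converts the power law to recruitment directly on
the response-rate scale — response rate = baseline × RQ^slope, so doubling
burden means asking 2^0.594 ≈ 1.51× more people, the same conversion that
turns the fitted odds law into a recruitment multiplier. The odds-scale
alternative (`"odds"`, via `apply_to_rate`) is available; note that with a
high baseline (default 0.97, motivated by the ~99% follow-up achievable
with minimal-burden measures) the odds model compresses response
differences so strongly that the non-response penalty never reorders the
curves, which is why it is not the default. Lost participants are billed at
the full unit cost by default (`lost_cost_equals_followed`); setting it
false bills only followed-up participants.

Qualitative behaviour under the defaults: without the penalty every cheap
measure undercuts the gold standard once the population SD exceeds a small
threshold (the even-M scales, whose midpoints straddle the population mean,
cross last, near SD ≈ 1.5), and more categories always help at moderate SD;
charging for non-response reverses the ordering so the 3-category scale is
cheapest. These orderings are asserted in the test suite.

## Numerical notes

- pmfs are validated to sum to 1 within 1e−12.
- REML optimisation: bounded on [0, max(10·var(y), 10·max v_i, 1)] with
  xatol 1e−10; the boundary value is compared against the interior optimum.
- Percentage reductions are reported against the non-measurement variance
  of the *same* distribution and range; they can be negative.
- The recovery study in the tests uses 500 replicates of K = 40 trials —
  large enough that the Monte-Carlo error of the mean slope (~0.007) is
  well inside the asserted ±0.03 band.
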