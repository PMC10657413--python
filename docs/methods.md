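# Methods

## Growth model and estimation

Each animal's tumor-volume series is modeled as simple exponential
growth, `V(t) = V₀ e^{rt}`, with `t` in integer days since
randomization (Day 0 = randomization and first dose). The rate `r` is
estimated per animal by ordinary least squares of `ln V` on day — the
canonical closed-form reading of an exponential model, exact on
noiseless data and correctly specified when measurement noise is
multiplicative lognormal. Nonlinear least squares on the volume scale
is deliberately not offered: it changes the estimand's weighting
without a compelling gain for thrice-weekly caliper data.

Volumes are floored at a configurable `floor` (default **1 mm³**)
before the log transform. A recorded 0 means "no palpable tumor"
(complete response), and the log is undefined there; flooring lets CR
animals contribute the strongly negative, finite rates they should.
Fits touching the floor carry `floored=True` so sensitivity analyses
(different floors, excluding floored animals) are one filter away.

A "Day d" analysis uses the window `[0, d]` — all measurements from
randomization through day d. With a single per-animal exponential
model this cumulative window is the only internally consistent choice;
the day is exposed as a parameter rather than fixed.

Animals removed at a humane endpoint contribute the measurements they
have; nothing is imputed. This is a known source of bias when fast
growers exit early — it truncates exactly the largest rates — and is
the main reason short analysis windows (ending before substantial
dropout) are preferable for rate comparisons. Animals with fewer than
two usable points are excluded from arm summaries with a logged
warning; reported `n` reflects exclusions.

Arm summaries use the arithmetic mean of per-animal rates, the
between-animal SE (sample SD / √n) and df = n − 1. The within-animal
OLS slope SE is reported per fit but not propagated: each animal's
fitted rate is treated as that animal's datum, and arm-level inference
rests on between-animal dispersion, which dominates under realistic
heterogeneity.

## GRI and its test

`GRI = 100 · (μ_control − μ_treatment) / μ_vehicle` (percent). The
normalizer is kept as a separate argument because a study may compare
two active arms while normalizing by the vehicle arm; in the common
case they coincide and the API defaults vehicle to control. GRI is
unitless in time (a ratio of rates) and antisymmetric under swapping
treatment and control.

The accompanying p-value is a two-sided Welch (unequal-variance)
two-sample t-test on the per-animal rates. No test is canonical here;
Welch on rates is chosen because the comparison object is explicitly
the arms' mean growth rates, and the unequal-variance form costs
almost nothing when variances happen to be equal.

## Synergy score

For a control / A / B / AB factorial design:

- score = `(μ_AB − μ_A − μ_B + μ_control) / μ_V · 100` (percent of the
  vehicle rate). Zero exactly when the combination sits at the
  additive prediction `μ_A + μ_B − μ_control`; the score is linear in
  `μ_AB` with slope `100/μ_V`.
- SE: the four arm means are independent, so the contrast's variance
  is the sum of their squared SEs; scaled by `100/|μ_V|`. The vehicle
  mean is treated as a **fixed normalizer** — no delta-method term for
  the denominator — consistent with degrees of freedom computed over
  the four groups only. A first-order delta-method variant that adds
  the vehicle term is available (`vehicle_error_term=True`) for
  sensitivity analysis; it always widens the SE.
- df: Welch–Satterthwaite over the four groups,
  `(Σ seᵢ²)² / Σ(seᵢ⁴/(nᵢ−1))`, which lies in
  `[min(nᵢ−1), Σ(nᵢ−1)]` and reduces to the two-sample Welch df when
  two SEs vanish.
- t = score/se, p two-tailed from t(df). If all four SEs are zero the
  statistic is undefined and the code raises rather than fabricating a
  p-value.

Classification at level α (default 0.05, the conventional
significance threshold): non-significant → *additive*; significant
negative → *synergistic*; significant positive → *sub-additive* when
`μ_AB < min(μ_A, μ_B)` (the combination still beats the best single
agent), else *antagonistic*.

## Secondary endpoints

- **T/C**: `100 · mean(V_treatment)/mean(V_control)` at a fixed day —
  the standard preclinical convention, flagged as such since multiple
  definitions circulate.
- **%BWL**: per animal `100·(w_d − w_0)/w_0` vs the pre-dose Day-0
  weight; per arm the day-wise mean; the *maximal mean %BWL* is the
  most negative arm-mean change, reported as a positive magnitude with
  its day (0 if the arm never drops below baseline on average).
- **Complete responders**: default policy `zero-sustained` — volume 0
  at the final assessment and at every measurement after first
  reaching 0 (no regrowth). A laxer `final-day-zero` policy is
  pluggable; the strict one matches how CR animals are selected for
  rechallenge (no palpable tumor through study end).

## Surrogate survival

Event time = first scheduled measurement day with volume ≥ the
endpoint threshold (default **1200 mm³**); no interpolation between
measurement days, since the data live on a thrice-weekly grid. An
animal that crosses and regresses keeps its first crossing. Animals
never crossing — including those euthanized early for non-tumor humane
reasons — are censored at their last observed day; that choice is a
documented convention, not an inference about why they left.

Kaplan–Meier curves and the two-sided unweighted log-rank test are
delegated to lifelines; the test suite cross-checks both against
brute-force implementations (direct product-limit risk-set
computation; per-event-time 2×2 hypergeometric accumulation with
tie-corrected variance). Greenwood confidence bands and Cox models are
out of scope. One invariant worth stating precisely: a censoring time
later than the last event is interchangeable with any other such time;
*adding* a late-censored animal, however, does change earlier survival
values, because it enlarges every risk set.

## Synthetic cohorts

`simulate_cohort` emulates the target study design:

| parameter | default | rationale |
|---|---|---|
| `baseline_mtv` | 30 mm³ | enrollment at ~30 mm³ mean tumor volume |
| `baseline_cv` | 0.25 | realistic spread of enrollment volumes |
| arm `rate` | 0.30/day (control) | vehicle-like growth: 30 → 1200 mm³ in ~12 days |
| arm `rate_sd` | 0.05/day | between-animal heterogeneity (~17% CV) |
| `noise_sd` | 0.10 | ~10% multiplicative caliper noise (log-scale SD) |
| schedule | days 0, 2, 4 + 7k | thrice-weekly measurement |
| `study_end_day` | 16 | a Day-16 rate analysis window |
| `endpoint_volume` | 1200 mm³ | surrogate-mortality threshold |
| `humane_removal_volume` | 2000 mm³ | removal keyed on latent volume |
| `detection_floor` | 1 mm³ | observed volumes below record as 0 |

Noise is multiplicative lognormal so the log-linear estimator is
correctly specified under the default generator; an additive-Gaussian
misspecification scenario (`noise_model="additive"`) exists for
robustness studies. Complete response is a rate switch (to
`cr_regression_rate` at `cr_onset_day`) rather than instantaneous
clearance, producing decaying series that exercise the flooring and
CR-detection logic. Humane removal triggers on the latent (noise-free)
volume — dropout is then reproducible and independent of the noise
draw on the removal day; the measurement on the crossing day is
recorded, then the animal exits. Body weights are constant (20 g)
unless an arm sets `weight_slope`. Identical (seed, config) pairs give
byte-identical tables.

`simulate_additive_null` overrides the AB arm's true mean rate to
`rate_A + rate_B − rate_control`, making the true synergy score
exactly 0 — the null used for type-I-error studies.

What the generator does **not** emulate: measurement-day jitter,
caliper digit preference, tumor ulceration and non-volume humane
removals, correlated noise within animals beyond the exponential
trend, immunological mechanism (arm effects are phenomenological rate
changes), and body-weight dynamics beyond a linear slope. Passing
tests therefore demonstrate correctness of the statistics under the
stated model, not robustness to every failure mode of real caliper
data — the additive-noise scenario and the floor/window/policy knobs
are the entry points for probing those.

## Operating characteristics and problem sizes

`run_operating_characteristics` replicates the whole pipeline
(simulate → fit → GRI/synergy/CR) with seeds spawned from a root seed
and reports rejection rates, bias, RMSE and Monte-Carlo SEs; it
refuses fewer than 100 replicates. The standard validation runs use
2000 replicates at n = 10/arm for the null rejection rate (binomial
99% band [0.03, 0.07] around α = 0.05) and 500 replicates for mean-GRI
recovery — sizes at which the Monte-Carlo SEs are a few tenths of a
percent and the checks complete in well under a minute. Note the GRI
estimator is a ratio of means and carries a small O(cv²) positive
bias (~0.1–0.3 points at these sizes), well inside Monte-Carlo noise.

## Numerical notes

- OLS is closed-form (centered normal equations); slope SE is 0 when
  n = 2 or residuals vanish.
- Degenerate normalizers (vehicle mean rate 0, control mean volume 0,
  no events, all-zero SEs) raise typed errors rather than returning
  inf/nan.
- The Welch p for two identical zero-variance arms is defined as 1
  (no evidence of difference) where the raw statistic would be 0/0.
- JSON sidecars serialize NaN and ±inf (e.g. median survival never
  reached) as null.
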