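# Methods

This note records the modelling assumptions behind `pmspline`, the
defaults that matter, the numerical choices, and what the synthetic
data generator does and does not emulate.

## Observation model

Each monitored work day contributes one time-series per size fraction;
a series is one complete 6–8 h shift of strictly positive mass
concentrations (µg/m³), modelled on the log10 scale.  For record *r*
of day *i*:

    log10 Y_ir ~ N( μ_i + x'_St α + x'_Env β + x'_Ev γ + ζ_i' b(t_ir), σ²_i )

* **Categorical effects.**  Station and environment are mutually
  exclusive states (exactly one of each per record); events are 0/1
  indicators that may overlap.  Reference coding is used throughout:
  the reference station and environment coefficients are fixed at 0
  and their columns omitted from the design, so every other
  coefficient is a log10 contrast against the reference.  When
  convergence is monitored, the reference coefficients are still
  counted as (degenerate, exactly-zero) entries, which is why the
  reference design of 45 stations / 8 environments / 10 events /
  24 days / 3 jobs monitors 45+8+10+24+24+3+3 = 117 parameters.
  Event effects are shared across days — one γ per event type.
* **Day intercepts and the job random effect.**  μ_i ~ N(m_j, τ²_j)
  with j = job(i).  The day intercept absorbs the job random effect;
  m_j and τ²_j are monitored hyperparameters (3 + 3 at the reference
  design).
* **Within-shift trend.**  ζ_i' b(t) is a per-day smooth trend in
  within-shift minutes, t = 0 at the day's first record.  b(t) is a
  clamped cubic B-spline basis with 8 equally spaced interior knots
  per shift (12 basis functions).  The basis is **column-centred
  within each day**: each basis column has its per-day record mean
  subtracted, so the fitted trend averages to exactly zero over the
  day's records for any ζ.  This removes the constant direction from
  the trend's column space and makes μ_i identifiable next to ζ_i
  without post-hoc recentring moves.  The generator centres its trend
  the same way.
* **Heteroscedastic days.**  σ²_i is day-specific; days differ visibly
  in volatility in this kind of campaign and a pooled variance would
  miscalibrate the predictive intervals.

## Priors and defaults

| parameter | prior | default | why |
|---|---|---|---|
| α, β, γ | N(0, s²) | s = 5 | weakly informative on log10 contrasts; s ∈ {3, 10} in the sensitivity analysis |
| m_j | N(0, 10²) | — | log10 µg/m³ baseline, effectively flat |
| σ²_i, τ²_j, σ²_ζ | Inverse-Gamma(0.01, 0.01) | — | the conventional weakly-informative BUGS-style variance prior; conjugate |
| ζ_i | N(0, σ²_ζ I) | — | common smoothness variance shared across days, learned from the data |
| chains / iterations / burn-in / thin | — | 3 / 10000 / 5000 / 1 | conservative defaults; every analysis in the tests and acceptance script states its own smaller settings |

The spline-coefficient variance σ²_ζ is given an Inverse-Gamma prior
rather than a half-Normal on σ_ζ: it keeps the entire sampler
conjugate, and at these data sizes (≥ 70 records per day informing 12
spline coefficients) the two choices are practically indistinguishable.

## Sampler

The posterior is sampled by a blocked Gibbs sampler; every full
conditional is available in closed form:

1. (α, β, γ) jointly — multivariate Normal (precision =
   X'WX + I/s², W = diag(1/σ²_day));
2. per day: ζ_i (multivariate Normal), μ_i (Normal), σ²_i
   (Inverse-Gamma);
3. per job: m_j (Normal), τ²_j (Inverse-Gamma);
4. σ²_ζ (Inverse-Gamma).

No step sizes, no tuning, no rejections; identical spec + seed gives
identical draws (each chain uses its own seed stream).  Initial values
are data-informed (per-day means and variances) with chain-specific
Gaussian jitter; a non-finite log-posterior at initialization raises
immediately with the offending values.  Correctness is pinned three
ways in the test suite: the log-likelihood against a brute-force
per-record Normal density sum (1e-10), the spline basis against an
independent Cox–de Boor recursion (1e-10), and the full posterior of a
small instance against an affine-invariant ensemble sampler run on the
same log-posterior density.

## Validation protocol

* **Convergence:** classic Gelman–Rubin R̂ (1992 between/within
  formula with the (n−1)/n correction, not split-R̂; a `split` variant
  is available).  Threshold R̂ < 1.1 — the conventional value; reports
  list every monitored parameter.  Constant (reference) chains are
  excluded as degenerate.
* **Autocorrelation:** sample ACF at lags 1–20 with lag-adjusted
  (1/(n−k)) denominators, so a perfectly anti-periodic chain reports
  acf(1) = −1 exactly.
* **Prior sensitivity:** full refits at s = 3 and s = 10; a
  coefficient is flagged when its posterior median moves by more than
  0.5 posterior SD — such coefficients are prior-dominated (typically
  categories with little data).
* **Posterior predictive check:** fraction of observed log10 records
  inside their 95% predictive interval (predictive draws include the
  day-specific observation noise); the observed-vs-predicted table is
  exportable for plotting.

## Calibration

Shift-level pairs (time-weighted mean of the raw optical series over
the filter's sampling interval, gravimetric value) are fitted with
three families: power g = a·m^b (OLS on log–log), linear g = a·m + c,
exponential g = a·e^{bm} (OLS on semi-log).  R² is computed **on the
original concentration scale** so the families are comparable — a
log-scale R² would structurally favour the power family.  Ties prefer
the power family, then fewer parameters.  Optional additive log(T) and
log(RH) terms are available in the power model (off by default); the
literature does not fix the covariates' functional form, so it is a
documented choice, not an assertion.  PM1 and PM0.3 are never
calibrated — there is no gravimetric measurement standard for them —
and the API refuses with `UnsupportedFractionError`.  A zero-variance
gravimetric target is reported as R² = 0 (uninformative) even when a
family fits it exactly.

## Synthetic campaign generator

The generator runs the observation model above *generatively* with
known parameters (stored as `GroundTruth`, JSON round-trip exact), on
schedules produced by qualitative job templates:

* *station agent* — one fixed home station, mostly ticket counter with
  short corridor/platform/outdoor breaks;
* *locomotive operator* — cabin traversal of the whole line, explicit
  `Tunnel` intervals between adjacent stations;
* *security guard* — foot/train patrol over a window of adjacent
  stations.

Every shift starts and ends in the reference environment (sampling
room).  Logbook intervals are half-open [start, end), contiguous, and
cover the shift exactly.  Event types follow a day-wise round-robin
plus random extras, which guarantees design completeness (every
category observed somewhere) by construction for the default
configuration; `generate_dataset` still verifies completeness and
resamples schedules (bounded retries) for unusual configurations.

Default generating values, chosen to mirror the structure of an
underground-rail campaign: 3 jobs × 8 days, 6 h shifts, mass records
every 300 s, counter records every 6 s; station effects drawn with SD
0.04 log10 (fold changes rarely beyond ~10%), environment SD 0.15,
event effects |N(0, 0.2)| (events are exposure peaks); job baselines
(0.55, 0.65, 0.60) log10 µg/m³ with intercept variance 0.04; per-day
residual variances uniform on (0.01, 0.09) (log10² scale); trend
coefficient SD 0.1 log10; fraction offsets (−1.05, 0, +0.09, +0.17)
log10 for PM0.3/PM1/PM2.5/PM10, putting PM0.3 more than an order of
magnitude below the coarser fractions; gravimetric truth
g = 2.5·m^1.05 with 10% lognormal noise (the optical reading
underestimates mass); counter totals 10³ × the OPC 0.25–0.7 µm band
with a shared latent trend.  The number-concentration spectrum is a
single lognormal mode at 0.30 µm (σ = 0.35 in log10 diameter) across
31 log-spaced channels.

What the generator does **not** emulate: aerosol microphysics
(coagulation, hygroscopic growth), instrument electronics or counting
efficiencies, correlated residuals beyond the smooth trend, and
station-to-station spatial correlation.  Passing tests therefore
demonstrate that the pipeline recovers the parameters of its own model
class under realistic dimensions and noise — not that the model is
correct for any particular field dataset.

An optional missing-data flag (`n_missing_days`) drops whole
day-series of real-time records, emulating instrument failures, to
test pipeline robustness.

## Device comparison

Channelized OPC number concentrations are integrated over a size band
with edge channels included **pro-rata by log-diameter width** (the
channels are log-spaced; locally flat dN/dlogD is the neutral
assumption; an all-or-nothing `nearest` mode is provided since a band
bound need not coincide with a channel edge).  Alignment averages the
finer series into the coarser grid's half-open windows and drops
incomplete pairs.  The comparison reports the ratio of totals, the
Pearson correlation of log10 values (concentrations span decades), and
the sign-agreement rate of first differences.

## Exposure summaries

Fold changes are 10^(posterior quantiles) at 2.5/50/97.5%; "elevated"
is strictly CI-low > 1, "borderline" is CI-low within δ = 0.02 below 1
(δ configurable).  Station-coefficient correlations use the posterior
**median** (configurable to the mean — the appropriate point estimate
is not standardised), pairwise deletion for missing covariates, and no
multiple-testing correction: the screen is exploratory, not
hypothesis-driven.  Station design types (A–G) are summarised as
per-type mean fold changes rather than an ANOVA.

## Problem sizes used in the shipped analyses

The test suite and the acceptance script run the model at a reduced
scale chosen to preserve the full hierarchical structure: 24 day-series
of 80 records (records every 270 s) with 12 station / 5 environment /
4 event categories, fitted with 3 chains × 3000 iterations (1000
burn-in, 2000 kept).  At this scale one fit takes ~20 s on one CPU and
effect-coefficient posteriors are informative enough that recovery,
convergence and predictive coverage are meaningful checks.  The
reference design (45/8/10, 24 days) is exercised structurally
(parameter counting, schedule generation, design completeness) without
a full MCMC run.

## Known limitations

* Station effects for a worker who spends an entire shift at one
  station are only weakly separated from that day's intercept; the
  hierarchy resolves the confounding but with wide intervals — real
  campaigns share this limitation (detection power depends on
  schedule mixing).
* The elevated-station rule (CI-low > 1) has the usual per-category
  false-flag rate; with many near-null stations occasional borderline
  flags are expected.
* Records spanning a station transition within one averaging window
  are assigned by window start time.
* The predictive check uses the training records (a posterior
  predictive p-value style check), not held-out days.
* Timezone handling is plain ISO-8601 parsing; no DST arithmetic.
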