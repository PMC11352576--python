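# Methods

## Statistical model

Bond lifetimes are modelled as exponential, `T_lt ~ Exp(λ_lt)`, and
fluorophore survival against photobleaching likewise, `T_b ~ Exp(λ_b)`.
Because unbinding and bleaching compete, the observable (apparent) lifetime
is `T_app ~ Exp(λ_lt + λ_b)`. Under stroboscopic illumination the bleaching
hazard accrues per exposure, not per unit time, so `λ_b = 1/(c_b·Δt)` with a
dimensionless bleaching constant `c_b`, giving

    τ_app(Δt) = 1 / (1/τ_lt + 1/(c_b·Δt)),   τ_lt = 1/λ_lt.

The model assumes (i) single-exponential unbinding (no conformational
heterogeneity or multi-state kinetics), (ii) bleaching proportional to the
exposure count, and (iii) independence of the two processes. For
non-exponential dwell times neither the memorylessness arguments below nor
the closed-form `τ_app(Δt)` relation hold.

## Likelihood for track lengths

A track observed for `n_i` frames at interval `Δt` has observed duration
`t_i = (n_i − 1)·Δt`. Its likelihood contribution handles three facts:

1. *Interval censoring of the endpoint.* A vanishing track ended somewhere in
   `(t_i, t_i + Δt)`.
2. *Unknown start.* Binding generally precedes the first detected frame; by
   memorylessness of the exponential the unknown pre-history conditions out
   exactly, so no start-time correction appears.
3. *Minimum track length.* Tracks shorter than `n_min` frames are discarded
   against noise, a left truncation at `t_min = (n_min − 1)·Δt` handled by
   conditioning on `T_app ≥ t_min`.

Per track (log space, used verbatim in the code to avoid cancellation when
`Δt ≪ τ`):

    vanishing:  log ℓ_i = −(t_i − t_min)/τ + log(1 − e^{−Δt/τ})
    censored:   log ℓ_i = −(t_i − t_min)/τ

The MLE `τ̂_app` maximizes `Σ_i log ℓ_i`. We optimize over `log τ` (automatic
positivity) with bounded derivative-free minimization, starting from the
bracket `[0.1, 10] × (mean(t_i − t_min) + Δt/2)` and doubling an edge up to
12 times when the maximizer lands on it. The standard error comes from the
observed Fisher information, `SE = (−∂²logℓ/∂τ²)^{−1/2}`, with a central
finite difference of relative step `1e−4`. The test suite cross-checks both
the estimate and the SE against lifelines' interval-censored exponential
fitter and against an independent grid-plus-golden-section search.

Degenerate inputs: an empty dataset and an all-censored dataset are errors
(the latter has a monotone likelihood with no finite maximizer). A dataset in
which *every* track is a vanishing minimum-length track with
`t_i = t_min = 0` also has no interior maximum — the likelihood
`(1 − e^{−Δt/τ})^n` increases without bound as `τ → 0` — and raises an
estimation error rather than returning an arbitrary small number.

The *conventional* comparator `τ̂ = mean(t_i − t_min) + Δt/2` (half-interval
shift because the signal vanishes between two exposures) deliberately
includes censored tracks at their observed duration; that is precisely the
practice whose bias the survival treatment removes, and it is kept to
reproduce that bias in comparisons. Its SE is the standard error of the mean
of the shifted durations — used only as a fit weight.

## Curve fit for τ_lt and c_b

Apparent-lifetime estimates at several `Δt` are fit to `τ_app(Δt)` by
weighted non-linear least squares (`scipy.optimize.curve_fit`), minimizing
`Σ ((τ̂_app,i − model)/SE_i)²`. Standard errors are treated as absolute
sigmas: the parameter covariance is *not* rescaled by reduced chi-square,
since the weights come from a likelihood and carry an absolute scale.
Initialization: `τ_lt⁰ = 1.5·max(τ̂_app)`, `c_b⁰ = τ̂_app(Δt_min)/Δt_min`.
Parameters are unconstrained so that pathological data can drive the
optimizer to a negative lifetime, which is then *flagged* (`failed = true`,
reason `large_negative_value` for any `τ_lt < 0` — a negative decay time is
unphysical regardless of magnitude) instead of being masked by bounds.
Non-convergence and non-finite covariance entries are flagged analogously.
The uncertainty band substitutes parameters ± one SE into the model; if a
minus-SE parameter is non-positive the lower curve is clamped at zero.

## Simulator

Synthetic tracks come from a two-state telegraph process: alternating on/off
dwell times drawn from exponentials with decay times `τ_app` (set by the
model above, so the simulated data embed the exact bleaching physics) and
`τ_off`. The initial state is drawn from the stationary distribution
`P(on) = τ_app/(τ_app + τ_off)` and a burn-in precedes sampling, so the
observation window is statistically stationary. Trajectories are sampled at
`n_samp` instants separated by `Δt`; each maximal run of consecutive
on-samples becomes one track with `frame_count` equal to the run length.
Runs touching the window end are right-censored; runs touching only the
window start are not — their residual length is, by memorylessness,
distributed like a fresh track, which is exactly how the likelihood treats
them. One trajectory may contribute several runs (finite `τ_off`), mirroring
how a tracker segments reappearing signals.

Defaults define the standard study conditions: `τ_lt = 10 s`, `c_b = 30`
(typical of experimental values), `τ_off = 1000 s`, burn-in `2000 s`.
The window length defaults to `n_samp = ceil(6·τ_app(Δt)/Δt)` — about six
apparent lifetimes, deliberately short so that a substantial fraction of
tracks touch a window edge and the censoring machinery is genuinely
exercised; it is configurable per `Δt`. Simulated datasets default to
`n_min = 1` (simulation produces no shot noise, so no track need be
discarded); for CSV import of experimental-style tables the default is
`n_min = 2`, since a one-frame signal cannot be distinguished from noise.

`simulate_dataset` generates trajectories in vectorized batches (drawing
dwell-time blocks per trajectory matrix row, locating sample instants by
cumulative-time comparison, and extracting runs with a padded-diff scan);
`simulate_state_trajectory`/`sample_trajectory` are the scalar reference
path, and a two-sample test verifies the two routes draw from the same
run-length and censoring distributions. Datasets are reproducible from a
single integer seed (per-interval generators derive from the seed and the
interval's index).

What the simulator does *not* emulate: localization/tracking errors, blinking
of fluorophores, background false positives, intensity-based filtering, and
spatial effects (diffusion out of the field of view, clustering). Passing
tests therefore demonstrate correctness of the statistical treatment given
ideal track extraction, not robustness to upstream image-analysis errors.

## Replicated studies

An *experiment* simulates one dataset per recording interval, estimates
`τ_app` with both methods and fits the curve twice. A *study* repeats this
with distinct derived seeds and reports mean ± std of the fitted `τ_lt` per
method, excluding failed fits from the moments while counting them
separately (a failed fit carries no usable parameter value). An estimation
failure at any single interval marks that experiment's fit failed rather
than aborting the study. Canned interval sets probe the steep part
(0.05–0.4 s), the bend (0.25–3 s) and the flat part (2–6 s) of the
`τ_app(Δt)` curve for a 10 s lifetime; dataset-size categories use 50/100/200
tracks per interval (fixed counts, not Poisson-jittered, for sharper tests).

## Problem sizes and tolerances

Validation runs use 2500-track datasets for single-condition checks and
100-experiment studies for the replicated conditions; with these sizes the
means of fitted lifetimes are stable to roughly ±0.1–0.3 s across seeds,
which is the basis of the ~10% assertion bands in the end-to-end tests.
Optimizer agreement with the grid oracle is asserted at 1e−6 relative;
noise-free curve recovery at 1e−6 relative; the interval-censored MLE
matches lifelines to 1e−5. Interval equality of `Δt` for grouping CSV rows
is textual, not floating-tolerance: a recording interval is an instrument
setting, not a measurement.

## Known limitations

* Single-exponential kinetics only; mixtures or catch/slip-bond behaviour
  require a different likelihood and `τ_app(Δt)` relation.
* The bleaching constant is assumed interval-independent; intensity-dependent
  bleaching or triplet blinking would violate `λ_b ∝ 1/Δt`.
* The conventional estimator's numerical value depends on the
  observation-window length, so comparisons with other window policies shift
  its bias (the survival estimate is insensitive to this by construction).
* Fit failures are diagnosed, not repaired; with as few as two intervals the
  covariance is frequently singular and the fit is reported as failed.
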