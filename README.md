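# fretlife

Photobleaching-corrected receptor–ligand bond lifetimes from single-molecule
FRET track lengths.

## The problem

In smFRET binding assays (e.g. TCR–pMHC on supported lipid bilayers) a FRET
signal is visible only while receptor and ligand are bound, so the length of a
single-molecule track measures the bond duration. Two observational artifacts
bias naive analysis of these track lengths:

* **Photobleaching.** A track can end because a fluorophore bleached, not
  because the bond broke. Under stroboscopic illumination fluorophores are
  excited only during frame acquisitions, so the bleaching rate is
  proportional to the frame rate: `λ_b = 1/(c_b·Δt)` for recording interval
  `Δt` and a dimensionless bleaching constant `c_b`.
* **The finite observation window.** Tracks still visible in the last frame
  are right-censored; dropping or truncating them biases lifetimes low.

Modelling bond lifetime and fluorophore survival as competing exponential
processes, the *apparent* lifetime observed at interval `Δt` is

```
τ_app(Δt) = 1 / (1/τ_lt + 1/(c_b·Δt))
```

where `τ_lt` is the characteristic bond lifetime of interest. The package

1. estimates `τ_app` per recording interval by maximum likelihood, treating
   each track as interval-censored (the signal vanished somewhere within one
   frame interval), right-censoring window-surviving tracks, and conditioning
   on the minimum accepted track length `n_min` (left truncation);
2. fits the curve above to the `(Δt, τ_app)` pairs by weighted non-linear
   least squares to recover `τ_lt` and `c_b` with standard errors;
3. provides a two-state (on/off) telegraph-process simulator with
   stroboscopic sampling to validate the whole pipeline against known ground
   truth, including the "conventional" shifted-mean estimator
   `τ_app = mean(t_i − t_min) + Δt/2` as the biased comparator.

It is aimed at experimentalists quantifying 2D receptor–ligand kinetics from
single-molecule tracking data, and at method developers who need a reference
implementation of censoring-aware dwell-time analysis.

## Worked example

```python
from fretlife import (SimulationConfig, simulate_dataset,
                      estimate_apparent_lifetime, conventional_mle,
                      fit_characteristic_lifetime)

config = SimulationConfig(tau_lt=10.0, c_b=30.0,
                          target_tracks_per_dt=2500, seed=7)
surv, conv = [], []
for dt in config.delta_t_set:          # (0.25, 0.5, 1.0, 2.0, 3.0) s
    ds = simulate_dataset(config, dt)
    surv.append(estimate_apparent_lifetime(ds))
    conv.append(conventional_mle(ds))

print(f"tau_app at dt=3 s: {surv[-1].tau_app:.2f} +/- {surv[-1].std_error:.2f} s")
fit = fit_characteristic_lifetime(surv)
print(f"survival fit:      tau_lt = {fit.tau_lt:.2f} +/- {fit.se_tau_lt:.2f} s, "
      f"c_b = {fit.c_b:.1f}")
fit_c = fit_characteristic_lifetime(conv)
print(f"conventional fit:  tau_lt = {fit_c.tau_lt:.2f} +/- {fit_c.se_tau_lt:.2f} s")
```

prints

```
tau_app at dt=3 s: 9.10 +/- 0.20 s
survival fit:      tau_lt = 10.03 +/- 0.19 s, c_b = 29.7
conventional fit:  tau_lt = 8.67 +/- 0.15 s
```

The true apparent lifetime at `Δt = 3 s` is 9.0 s and the true bond lifetime
is 10 s: the censoring-aware estimate recovers both within one standard
error, while the conventional estimator underestimates the bond lifetime by
more than 10% — the photobleaching correction alone cannot repair the
censoring bias.

The same pipeline is available from a shell: `fretlife simulate`,
`fretlife estimate`, `fretlife fit`, `fretlife study`, and
`fretlife reproduce {single-interval,interval-sets,dataset-sizes}` for the
canned characterization studies. Estimator classes follow scikit-learn
conventions (`ApparentLifetimeMLE`, `PhotobleachingCurveFitter`; `fit`,
`get_params`, fitted attributes with trailing underscores).

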