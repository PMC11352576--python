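"""Interval-censored exponential MLE: likelihood values, optimizer, comparator."""

import math

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from fretlife import (
    ApparentLifetimeMLE,
    EstimationError,
    LikelihoodContext,
    conventional_mle,
    estimate_apparent_lifetime,
    log_likelihood,
)

from conftest import make_dataset, random_dataset


def ctx_of(dataset):
    return LikelihoodContext.from_dataset(dataset)


def grid_golden_mle(ctx):
    """Independent oracle: dense grid scan + golden-section refinement."""
    taus = np.geomspace(1e-3 * ctx.delta_t, 1e5 * ctx.delta_t, 4000)
    lls = np.array([log_likelihood(t, ctx) for t in taus])
    i = int(np.argmax(lls))
    res = minimize_scalar(
        lambda t: -log_likelihood(t, ctx),
        bracket=(taus[max(i - 1, 0)], taus[i], taus[min(i + 1, len(taus) - 1)]),
        method="golden",
        options={"xtol": 1e-12},
    )
    return float(res.x)


@pytest.mark.parametrize(
    "frame_count, censored, nmin, tau, expected",
    [
        # vanishing track, n=2, nmin=1: log(0.5 * (1 - 0.5)) at tau = 1/ln 2
        (2, False, 1, 1 / math.log(2), math.log(0.25)),
        # censored track with n = nmin contributes nothing
        (3, True, 3, 0.7, 0.0),
        (3, True, 3, 5.0, 0.0),
        # vanishing track at t = t_min = 0: log(1 - e^-1)
        (1, False, 1, 1.0, math.log(1 - math.exp(-1))),
    ],
)
def test_log_likelihood_hand_computed(frame_count, censored, nmin, tau, expected):
    ds = make_dataset([frame_count], [censored], delta_t=1.0, nmin=nmin)
    assert log_likelihood(tau, ctx_of(ds)) == pytest.approx(expected, rel=1e-12)


def test_log_likelihood_domain_errors():
    ds = make_dataset([2], [False])
    with pytest.raises(ValueError):
        log_likelihood(0.0, ctx_of(ds))
    with pytest.raises(ValueError):
        log_likelihood(
            1.0, LikelihoodContext(np.array([]), np.array([], bool), 1.0, 0.0)
        )


def test_single_track_mle_is_analytic():
    # maximizing u - u^2 with u = exp(-1/tau) gives u = 1/2, tau = 1/ln 2
    ds = make_dataset([2], [False], delta_t=1.0, nmin=1)
    est = estimate_apparent_lifetime(ds)
    assert est.tau_app == pytest.approx(1 / math.log(2), rel=1e-6)
    assert est.method == "survival"
    assert est.n_tracks == 1 and est.n_censored == 0
    assert est.std_error > 0


def test_all_censored_is_unbounded():
    ds = make_dataset([3, 5], [True, True])
    with pytest.raises(EstimationError, match="unbounded"):
        estimate_apparent_lifetime(ds)


def test_empty_dataset_rejected():
    ds = make_dataset([], [])
    with pytest.raises(ValueError):
        estimate_apparent_lifetime(ds)
    with pytest.raises(ValueError):
        conventional_mle(ds)


@pytest.mark.parametrize("seed", range(8))
def test_optimizer_matches_grid_oracle(seed):
    """Bounded log-space optimization agrees with grid + golden section."""
    rng = np.random.default_rng(seed)
    nmin = int(rng.integers(1, 4))
    ds = random_dataset(rng, delta_t=float(rng.choice([0.25, 1.0, 3.0])), nmin=nmin)
    est = estimate_apparent_lifetime(ds)
    oracle = grid_golden_mle(ctx_of(ds))
    assert est.tau_app == pytest.approx(oracle, rel=1e-6)


@pytest.mark.parametrize("seed", range(6))
def test_estimate_is_a_maximum(seed):
    rng = np.random.default_rng(100 + seed)
    ds = random_dataset(rng)
    est = estimate_apparent_lifetime(ds)
    ctx = ctx_of(ds)
    ll_hat = log_likelihood(est.tau_app, ctx)
    assert ll_hat >= log_likelihood(est.tau_app / 2, ctx)
    assert ll_hat >= log_likelihood(est.tau_app * 2, ctx)
    assert est.log_likelihood_at_max == pytest.approx(ll_hat, abs=1e-9)


@pytest.mark.parametrize("seed", range(6))
def test_appending_censored_track_never_decreases_estimate(seed):
    rng = np.random.default_rng(200 + seed)
    ds = random_dataset(rng)
    before = estimate_apparent_lifetime(ds).tau_app
    extra = int(rng.integers(1, 30))
    bigger = make_dataset(
        list(ds.frame_counts) + [extra],
        list(ds.censored) + [True],
        delta_t=ds.delta_t,
        nmin=ds.min_frame_count,
    )
    after = estimate_apparent_lifetime(bigger).tau_app
    assert after >= before - 1e-9


def test_continuum_limit_matches_midpoint_mean(rng):
    """With dt << tau, no censoring and t_min = 0, the MLE approaches the
    midpoint-corrected exponential mean."""
    tau_true, dt = 10.0, 0.05
    t = np.floor(rng.exponential(tau_true, size=4000) / dt) * dt
    ds = make_dataset((t / dt + 1).astype(int), np.zeros(len(t), bool), delta_t=dt)
    est = estimate_apparent_lifetime(ds)
    assert dt <= est.tau_app / 100
    midpoint = (ds.durations + dt / 2).mean()
    assert est.tau_app == pytest.approx(midpoint, rel=0.01)


def test_matches_lifelines_interval_censoring():
    """Estimate and SE agree with lifelines' interval-censored exponential fit."""
    lifelines = pytest.importorskip("lifelines")
    rng = np.random.default_rng(7)
    counts = rng.geometric(0.2, size=400) + 1
    censored = rng.random(400) < 0.25
    ds = make_dataset(counts, censored, delta_t=2.0, nmin=2)
    est = estimate_apparent_lifetime(ds)

    t = ds.durations - ds.t_min
    lower, upper = t, np.where(ds.censored, np.inf, t + ds.delta_t)
    ef = lifelines.ExponentialFitter().fit_interval_censoring(lower, upper)
    assert est.tau_app == pytest.approx(float(ef.lambda_), rel=1e-5)
    assert est.std_error == pytest.approx(
        float(ef.summary.loc["lambda_", "se(coef)"]), rel=1e-3
    )


@pytest.mark.parametrize(
    "counts, nmin, dt, expected",
    [([2, 3, 4], 2, 1.0, 1.5), ([4], 4, 2.0, 1.0)],
)
def test_conventional_mle_shifted_mean(counts, nmin, dt, expected):
    ds = make_dataset(counts, [False] * len(counts), delta_t=dt, nmin=nmin)
    est = conventional_mle(ds)
    assert est.tau_app == pytest.approx(expected)
    assert est.method == "conventional"


def test_conventional_mle_ignores_censoring():
    # censored tracks enter with their observed duration, shrinking the mean
    base = make_dataset([2, 3, 4], [False] * 3)
    flagged = make_dataset([2, 3, 4], [False, False, True])
    assert conventional_mle(base).tau_app == conventional_mle(flagged).tau_app


def test_estimator_is_sklearn_compatible():
    mle = ApparentLifetimeMLE(method="conventional")
    assert mle.get_params()["method"] == "conventional"
    mle.set_params(method="survival")
    ds = make_dataset([2, 5, 3], [False, True, False])
    fitted = mle.fit(ds)
    assert fitted is mle and fitted.tau_app_ > 0


def test_degenerate_all_minimum_length_vanishing_tracks():
    # every track at t_i = t_min = 0 and vanishing: the likelihood
    # (1 - exp(-dt/tau))^n is monotone decreasing in tau, so no finite
    # maximizer exists and estimation must refuse rather than return 0
    ds = make_dataset([1, 1, 1], [False] * 3, delta_t=2.0, nmin=1)
    with pytest.raises(EstimationError):
        estimate_apparent_lifetime(ds)
    # one longer track restores an interior maximum
    mixed = make_dataset([1, 1, 2], [False] * 3, delta_t=2.0, nmin=1)
    est = estimate_apparent_lifetime(mixed)
    assert np.isfinite(est.tau_app) and est.tau_app > 0
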