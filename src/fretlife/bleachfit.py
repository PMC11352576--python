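"""Photobleaching correction: infer the bond lifetime from tau_app(delta_t).

Under stroboscopic illumination fluorophores are excited only during frame
acquisitions, so the photobleaching rate is proportional to the acquisition
rate: ``lambda_b = 1 / (c_b * delta_t)``.  Combined with the unbinding rate
``1 / tau_lt`` this gives the apparent lifetime as a function of the recording
interval::

    tau_app(delta_t) = 1 / (1/tau_lt + 1/(c_b * delta_t))

Fitting this curve to apparent-lifetime estimates obtained at several
recording intervals, weighted by their standard errors, recovers the
characteristic bond lifetime ``tau_lt`` and the bleaching constant ``c_b``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import OptimizeWarning, curve_fit
from sklearn.base import BaseEstimator

from .trackdata import ApparentLifetimeEstimate, LifetimeFitResult

__all__ = [
    "tau_app_model",
    "ApparentLifetimeSeries",
    "PhotobleachingCurveFitter",
    "fit_characteristic_lifetime",
    "uncertainty_band",
]


def tau_app_model(delta_t, tau_lt, c_b):
    """Apparent lifetime ``1 / (1/tau_lt + 1/(c_b*delta_t))`` in seconds.

    All arguments must be positive; ``delta_t`` may be an array.
    """
    delta_t = np.asarray(delta_t, dtype=float)
    if np.any(delta_t <= 0):
        raise ValueError("delta_t must be positive")
    if not (tau_lt > 0 and c_b > 0):
        raise ValueError("tau_lt and c_b must be positive")
    out = 1.0 / (1.0 / tau_lt + 1.0 / (c_b * delta_t))
    return float(out) if out.ndim == 0 else out


def _model_unchecked(delta_t, tau_lt, c_b):
    # used inside the optimizer, which may probe unphysical parameter values
    with np.errstate(divide="ignore", invalid="ignore"):
        return 1.0 / (1.0 / tau_lt + 1.0 / (c_b * delta_t))


@dataclass
class ApparentLifetimeSeries:
    """Pairs (delta_t, tau_app, std_error) feeding the weighted curve fit."""

    delta_t: np.ndarray
    tau_app: np.ndarray
    std_error: np.ndarray

    def __post_init__(self) -> None:
        self.delta_t = np.asarray(self.delta_t, dtype=float)
        self.tau_app = np.asarray(self.tau_app, dtype=float)
        self.std_error = np.asarray(self.std_error, dtype=float)
        if not (self.delta_t.shape == self.tau_app.shape == self.std_error.shape):
            raise ValueError("delta_t, tau_app and std_error must share a shape")

    @classmethod
    def from_estimates(
        cls, estimates: Iterable[ApparentLifetimeEstimate]
    ) -> "ApparentLifetimeSeries":
        ests = list(estimates)
        return cls(
            delta_t=np.array([e.delta_t for e in ests]),
            tau_app=np.array([e.tau_app for e in ests]),
            std_error=np.array([e.std_error for e in ests]),
        )


class PhotobleachingCurveFitter(BaseEstimator):
    """Weighted non-linear least-squares fit of the tau_app(delta_t) curve.

    The fit minimizes ``sum(((tau_app_i - model(delta_t_i)) / se_i)**2)``.
    Standard errors are absolute measurement sigmas: the parameter covariance
    is taken from the fit directly, not rescaled by reduced chi-square.
    Parameters are unconstrained so that a negative fitted lifetime is
    *detected* (and flagged as a failure) rather than masked by bounds.

    Attributes
    ----------
    tau_lt_, c_b_ : float
    se_tau_lt_, se_c_b_ : float
    covariance_ : (2, 2) ndarray
    failed_ : bool
    failure_reason_ : {"none", "no_convergence", "infinite_covariance",
        "large_negative_value"}
    result_ : LifetimeFitResult
    """

    def __init__(self, maxfev: int = 10000):
        self.maxfev = maxfev

    def fit(self, X, y=None, sigma=None) -> "PhotobleachingCurveFitter":
        if isinstance(X, ApparentLifetimeSeries):
            series = X
        else:
            if y is None or sigma is None:
                raise ValueError(
                    "pass an ApparentLifetimeSeries, or delta_t, tau_app and sigma"
                )
            series = ApparentLifetimeSeries(np.ravel(X), y, sigma)

        dt, tau, se = series.delta_t, series.tau_app, series.std_error
        if dt.size < 2:
            raise ValueError("need >= 2 recording intervals for a 2-parameter fit")
        if np.unique(dt).size != dt.size:
            raise ValueError("recording intervals must be distinct")
        if np.any(se <= 0):
            raise ValueError("std_error weights must be positive")

        # cheap initial guess inside the basin for short/medium/long regimes
        tau_lt0 = 1.5 * float(tau.max())
        i_min = int(np.argmin(dt))
        c_b0 = float(tau[i_min] / dt[i_min])

        failed = False
        reason = "none"
        popt = np.array([math.nan, math.nan])
        pcov = np.full((2, 2), math.nan)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", OptimizeWarning)
                warnings.simplefilter("ignore", RuntimeWarning)
                popt, pcov = curve_fit(
                    _model_unchecked,
                    dt,
                    tau,
                    p0=(tau_lt0, c_b0),
                    sigma=se,
                    absolute_sigma=True,
                    maxfev=self.maxfev,
                )
        except RuntimeError:
            failed = True
            reason = "no_convergence"

        if not failed and not np.all(np.isfinite(pcov)):
            failed = True
            reason = "infinite_covariance"
        if not failed and popt[0] < 0:
            failed = True
            reason = "large_negative_value"

        self.tau_lt_ = float(popt[0])
        self.c_b_ = float(popt[1])
        self.covariance_ = pcov
        with np.errstate(invalid="ignore"):
            self.se_tau_lt_ = float(np.sqrt(pcov[0, 0]))
            self.se_c_b_ = float(np.sqrt(pcov[1, 1]))
        self.failed_ = failed
        self.failure_reason_ = reason
        self.result_ = LifetimeFitResult(
            tau_lt=self.tau_lt_,
            c_b=self.c_b_,
            se_tau_lt=self.se_tau_lt_,
            se_c_b=self.se_c_b_,
            covariance=pcov,
            failed=failed,
            failure_reason=reason,
        )
        return self

    def predict(self, delta_t) -> np.ndarray:
        """Model apparent lifetimes at the given recording intervals."""
        if self.failed_:
            raise ValueError("cannot predict from a failed fit")
        return tau_app_model(np.asarray(delta_t, dtype=float), self.tau_lt_, self.c_b_)


def fit_characteristic_lifetime(
    series: ApparentLifetimeSeries | Sequence[ApparentLifetimeEstimate],
) -> LifetimeFitResult:
    """Fit the photobleaching model to an apparent-lifetime series (wrapper)."""
    if not isinstance(series, ApparentLifetimeSeries):
        series = ApparentLifetimeSeries.from_estimates(series)
    return PhotobleachingCurveFitter().fit(series).result_


def uncertainty_band(
    fit: LifetimeFitResult, delta_t_grid
) -> tuple[np.ndarray, np.ndarray]:
    """Lower/upper model curves at fit parameters -/+ one standard error.

    If a minus-one-sigma parameter is non-positive the lower curve is clamped
    at zero (the model is undefined there).
    """
    if fit.failed:
        raise ValueError("cannot compute an uncertainty band for a failed fit")
    grid = np.asarray(delta_t_grid, dtype=float)
    if np.any(grid <= 0):
        raise ValueError("delta_t grid values must be positive")
    lo_tau, lo_cb = fit.tau_lt - fit.se_tau_lt, fit.c_b - fit.se_c_b
    if lo_tau <= 0 or lo_cb <= 0:
        lower = np.zeros_like(grid)
    else:
        lower = tau_app_model(grid, lo_tau, lo_cb)
    upper = tau_app_model(grid, fit.tau_lt + fit.se_tau_lt, fit.c_b + fit.se_c_b)
    return lower, upper
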