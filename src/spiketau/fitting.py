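"""Intrinsic-timescale extraction by single-exponential fitting.

The intrinsic timescale tau is the decay constant of the (autocorrelation)
curve, obtained by nonlinear least squares of

    y(t) = a * (exp(-b*t) + c)

over lag times t in ms, with b constrained positive; tau = 1/b.  Note the
offset sits inside the parentheses, so the plateau of the curve is a*c.

The standard error of tau follows from the one of b by error propagation
(sigma_tau = sigma_b / b^2) and its confidence interval uses the Student-t
quantile at dof = n_points - 3.

Fits are classified as ``ok``, ``fit_failed`` (NaN in the fitted range,
too few points, non-convergence, singular covariance) or ``negative_r2``
(converged but worse than predicting the mean).  A decay rate that lands
on its positivity bound is still a converged — absurdly slow — decay and
is classified by its R² like any other fit; the quality criteria
(confidence interval excluding zero, R² threshold) are what flag such
estimates downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import t as student_t

from .estimators import ACFCurve

__all__ = ["ExpFit", "fit_exponential", "tau_confidence_interval", "r_squared",
           "pooled_fit", "DEFAULT_CI_LEVEL"]

DEFAULT_CI_LEVEL = 0.95
_B_LOWER = 1e-6  # positivity bound on the decay rate, 1/ms


@dataclass(frozen=True)
class ExpFit:
    """Result of one exponential-decay fit.

    ``tau = 1/b`` (ms) and ``sigma_tau = sigma_b / b**2`` hold as
    identities whenever the fit converged.  ``ci`` is (level, lower,
    upper) in ms, or None when dof < 1.  ``status`` is one of
    {"ok", "fit_failed", "negative_r2"}; ``reason`` carries the failure
    detail.
    """

    amplitude: float = np.nan
    decay_rate: float = np.nan
    offset: float = np.nan
    tau: float = np.nan
    sigma_b: float = np.nan
    sigma_tau: float = np.nan
    ci: tuple[float, float, float] | None = None
    r_squared: float = np.nan
    n_points: int = 0
    status: str = "fit_failed"
    reason: str = ""

    @property
    def dof(self) -> int:
        return self.n_points - 3

    @property
    def ok(self) -> bool:
        return self.status == "ok"


def _model(t, a, b, c):
    return a * (np.exp(-b * t) + c)


def r_squared(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot; negative when the
    model is worse than the mean."""
    observed = np.asarray(observed, dtype=np.float64)
    predicted = np.asarray(predicted, dtype=np.float64)
    ss_tot = np.sum((observed - observed.mean()) ** 2)
    if observed.size < 2 or ss_tot == 0:
        raise ValueError("need >= 2 observations with nonzero variance")
    ss_res = np.sum((observed - predicted) ** 2)
    return float(1.0 - ss_res / ss_tot)


def _failed(reason: str, n_points: int = 0) -> ExpFit:
    return ExpFit(status="fit_failed", reason=reason, n_points=n_points)


def _fit_points(t: np.ndarray, y: np.ndarray, lag_step: float,
                ci_level: float) -> ExpFit:
    n = t.size
    if n < 4:
        return _failed("too_few_points", n)
    a0 = float(np.clip(y[0], 1e-3, 2.0))
    b0 = 1.0 / (5.0 * lag_step)
    p0 = (a0, b0, 0.0)
    try:
        popt, pcov = curve_fit(
            _model, t, y, p0=p0,
            bounds=([-np.inf, _B_LOWER, -np.inf], [np.inf, np.inf, np.inf]),
            method="trf", xtol=1e-8, ftol=1e-8, gtol=1e-8, max_nfev=5000,
        )
    except (RuntimeError, ValueError):
        return _failed("no_convergence", n)
    a, b, c = (float(v) for v in popt)
    var_b = pcov[1, 1]
    if not np.isfinite(var_b) or var_b < 0:
        return _failed("singular_covariance", n)
    sigma_b = float(np.sqrt(var_b))
    tau = 1.0 / b
    sigma_tau = sigma_b / b**2
    r2 = r_squared(y, _model(t, a, b, c))
    fit = ExpFit(amplitude=a, decay_rate=b, offset=c, tau=tau,
                 sigma_b=sigma_b, sigma_tau=sigma_tau, ci=None,
                 r_squared=r2, n_points=n,
                 status="ok" if r2 >= 0 else "negative_r2",
                 reason="" if r2 >= 0 else "negative_r2")
    if fit.dof >= 1:
        lo, hi = tau_confidence_interval(fit, ci_level)
        fit = replace(fit, ci=(ci_level, lo, hi))
    return fit


def fit_exponential(curve: ACFCurve, fit_start_lag: int = 1,
                    ci_level: float = DEFAULT_CI_LEVEL) -> ExpFit:
    """Fit y(t) = a*(exp(-b*t) + c) to a curve from ``fit_start_lag`` onward.

    Lag times are in ms, so tau comes out in ms.  A NaN anywhere in the
    fitted range excludes the curve (status ``fit_failed``, reason
    ``nan_in_curve``); by default the lag-0 point is dropped and the fit
    uses lags 1..nlags.
    """
    t = curve.lags[fit_start_lag:]
    y = curve.values[fit_start_lag:]
    if t.size == 0:
        return _failed("too_few_points")
    if np.isnan(y).any():
        return _failed("nan_in_curve", int(t.size))
    lag_step = float(t[1] - t[0]) if t.size > 1 else float(t[0] or 1.0)
    return _fit_points(t, y, lag_step, ci_level)


def tau_confidence_interval(fit: ExpFit, level: float = DEFAULT_CI_LEVEL
                            ) -> tuple[float, float]:
    """Symmetric Student-t interval tau ± t_{alpha/2, dof} * sigma_tau."""
    if fit.dof < 1:
        raise ValueError("confidence interval needs dof >= 1")
    if not np.isfinite(fit.sigma_tau):
        raise ValueError("fit has no standard error")
    q = student_t.ppf(1.0 - (1.0 - level) / 2.0, fit.dof)
    return float(fit.tau - q * fit.sigma_tau), float(fit.tau + q * fit.sigma_tau)


def pooled_fit(curves, fit_start_lag: int = 2,
               ci_level: float = DEFAULT_CI_LEVEL) -> ExpFit:
    """Single exponential fitted jointly to all NaN-free curves.

    Used for area-level (pooled) timescales: the (lag, value) points of
    every valid curve are stacked and fitted together, by default from
    lag index 2.
    """
    ts, ys, lag_step = [], [], None
    for c in curves:
        if c.has_nan:
            continue
        t = c.lags[fit_start_lag:]
        y = c.values[fit_start_lag:]
        if t.size == 0:
            continue
        ts.append(t)
        ys.append(y)
        if lag_step is None and t.size > 1:
            lag_step = float(t[1] - t[0])
    if not ts:
        return _failed("no_valid_curves")
    t = np.concatenate(ts)
    y = np.concatenate(ys)
    return _fit_points(t, y, lag_step or float(t[0] or 1.0), ci_level)
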