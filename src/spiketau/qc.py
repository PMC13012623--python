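"""Estimation-error and spike-train quality metrics.

Covers the relative estimation error (REE) against a known ground-truth
timescale, the local-variation (Lv) regularity statistic of inter-spike
intervals, and the three inclusion criteria commonly applied to timescale
estimates: a declining curve in the 50-200 ms range, a 95% confidence
interval that excludes zero, and a coefficient of determination of at
least 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .estimators import ACFCurve
from .fitting import ExpFit
from .hawkes import SpikeTrain

__all__ = [
    "QCRecord",
    "relative_estimation_error",
    "local_variation",
    "acf_decline_flag",
    "ci_excludes_zero",
    "qc_report",
    "R2_THRESHOLD",
    "DECLINE_WINDOW",
]

R2_THRESHOLD = 0.5
DECLINE_WINDOW = (50.0, 200.0)


@dataclass(frozen=True)
class QCRecord:
    """Inclusion criteria and rejection status for one fit."""

    declines_50_200: bool
    ci_excludes_zero: bool
    r2_pass: bool
    rejected: bool
    rejection_reason: str  # "none" | "fit_failed" | "negative_r2"


def relative_estimation_error(it_est: float, it_gt: float) -> float:
    """Signed percentage error (IT_e - IT_gt) / IT_gt * 100.

    The same formula with the full-signal estimate in place of the ground
    truth gives the pseudo-REE used on experimental data.  Interval
    summaries conventionally take the absolute value.
    """
    if it_gt <= 0:
        raise ValueError(f"ground-truth timescale must be > 0, got {it_gt}")
    if it_est is None or not np.isfinite(it_est):
        return float("nan")
    return (it_est - it_gt) / it_gt * 100.0


def local_variation(train: SpikeTrain | np.ndarray) -> float:
    """Local variation of the inter-spike intervals:

        Lv = 3/(n-1) * sum_i ((I_i - I_{i+1}) / (I_i + I_{i+1}))^2

    0 for perfectly regular trains, 1 in expectation for Poisson, above 1
    for bursty firing.  Invariant under uniform time rescaling.  NaN with
    fewer than 2 ISIs.
    """
    isis = train.isis if isinstance(train, SpikeTrain) else np.diff(np.asarray(train))
    n = isis.size
    if n < 2:
        return float("nan")
    ratio = (isis[:-1] - isis[1:]) / (isis[:-1] + isis[1:])
    return float(3.0 / (n - 1) * np.sum(ratio**2))


def acf_decline_flag(curve: ACFCurve, window: tuple[float, float] = DECLINE_WINDOW,
                     mode: str = "anchors") -> bool:
    """Does the curve decline over the given lag window?

    Default test ("anchors"): the value at the last lag <= window end is
    strictly below the value at the first lag >= window start, on the
    curve's native lag grid.  "monotone" requires every successive step in
    the window to be non-increasing with at least one strict decrease.
    NaN at an anchor lag fails the criterion.
    """
    lo, hi = window
    in_lo = np.flatnonzero(curve.lags >= lo)
    in_hi = np.flatnonzero(curve.lags <= hi)
    if in_lo.size == 0 or in_hi.size == 0 or in_lo[0] > in_hi[-1]:
        return False
    i, j = int(in_lo[0]), int(in_hi[-1])
    if mode == "anchors":
        v0, v1 = curve.values[i], curve.values[j]
        if np.isnan(v0) or np.isnan(v1):
            return False
        return bool(v1 < v0)
    if mode == "monotone":
        seg = curve.values[i:j + 1]
        if np.isnan(seg).any() or seg.size < 2:
            return False
        d = np.diff(seg)
        return bool(np.all(d <= 0) and np.any(d < 0))
    raise ValueError(f"unknown decline mode {mode!r}")


def ci_excludes_zero(fit: ExpFit) -> bool:
    """True iff the lower CI bound is strictly above zero."""
    if fit.ci is None:
        return False
    _, lo, _ = fit.ci
    return bool(lo > 0)


def qc_report(fit: ExpFit, curve: ACFCurve) -> QCRecord:
    """Assemble the inclusion criteria for one unit/method fit.

    A unit is rejected when its fit failed outright or converged with a
    negative coefficient of determination; the three pass-flags are only
    meaningful (and only true) for fits with status ok.
    """
    ok = fit.status == "ok"
    return QCRecord(
        declines_50_200=bool(ok and acf_decline_flag(curve)),
        ci_excludes_zero=bool(ok and ci_excludes_zero(fit)),
        r2_pass=bool(ok and np.isfinite(fit.r_squared) and fit.r_squared >= R2_THRESHOLD),
        rejected=not ok,
        rejection_reason="none" if ok else fit.status if fit.status == "negative_r2" else "fit_failed",
    )
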