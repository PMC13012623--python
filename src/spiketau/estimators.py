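"""Autocorrelation and autocorrelation-like curve estimators.

Four estimators of the spike-train autocorrelation are provided, two for
long unsegmented recordings and two for epoched (trial-based) data:

================  ==================  =========================
data              binned spike counts  raw spike times
================  ==================  =========================
unsegmented       ``acf_classic``      ``isttc_acf``
trials            ``pearsonr_trial_avg``  ``isttc_trials``
================  ==================  =========================

The spike time tiling coefficient (STTC) measures correlation between two
spike trains A and B from the fraction P_A of A's spikes lying within
``±dt`` of any spike of B (and vice versa), discounted by the fraction
T_A (T_B) of the signal covered by the ``±dt`` tiles of each train:

    STTC = 1/2 * ( (P_A - T_B)/(1 - P_A*T_B) + (P_B - T_A)/(1 - P_B*T_A) )

It is insensitive to firing rate, needs no binning, and equals 1 when a
train is compared with itself.  ``isttc_acf`` turns it into an
autocorrelation-like curve by correlating a train with lag-shifted,
truncated copies of itself; ``isttc_trials`` extends this to concatenated,
zero-padded trials with the T terms held fixed at their per-trial values
so the padding cannot bias the result.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .hawkes import SpikeTrain, TrialSet

__all__ = [
    "STTCConfig",
    "BinnedTrain",
    "ACFCurve",
    "bin_spike_train",
    "bin_trials",
    "tiling_fraction",
    "sttc",
    "sttc_fixed_t",
    "acf_classic",
    "isttc_acf",
    "pearsonr_trial_avg",
    "average_tiling",
    "concatenate_with_padding",
    "isttc_trials",
]


@dataclass(frozen=True)
class STTCConfig:
    """Estimator hyperparameters.

    dt : tiling half-window, ms.  lag_shift : increment between successive
    lags, ms.  nlags : number of nonzero lags.  bin_size : bin width for the
    count-based estimators, ms.  pad : silent gap inserted between
    concatenated trials, ms; must be at least one trial length so tiles
    never bridge a trial boundary.
    """

    dt: float = 25.0
    lag_shift: float = 50.0
    nlags: int = 20
    bin_size: float = 50.0
    pad: float = 3000.0

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.lag_shift <= 0 or self.bin_size <= 0:
            raise ValueError("dt, lag_shift and bin_size must be > 0")
        if self.nlags < 1:
            raise ValueError("nlags must be >= 1")

    @classmethod
    def default(cls) -> "STTCConfig":
        """The reference setting used throughout the benchmarks: curves over
        0-1000 ms with dt=25 ms, lag_shift=bin_size=50 ms, nlags=20,
        pad=3000 ms."""
        return cls()


@dataclass(frozen=True)
class BinnedTrain:
    """Spike counts over consecutive half-open bins of fixed width (ms)."""

    counts: np.ndarray
    bin_size: float

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 1:
            raise ValueError("counts must be 1-D")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts.astype(np.int64))
        if self.bin_size <= 0:
            raise ValueError("bin_size must be > 0")

    @property
    def n_bins(self) -> int:
        return int(self.counts.size)


@dataclass(frozen=True)
class ACFCurve:
    """Lag (ms) / value pairs from one estimator; values may contain NaN."""

    lags: np.ndarray
    values: np.ndarray
    method: str
    config: STTCConfig | None = None

    def __post_init__(self) -> None:
        lags = np.asarray(self.lags, dtype=np.float64)
        values = np.asarray(self.values, dtype=np.float64)
        if lags.shape != values.shape or lags.ndim != 1:
            raise ValueError("lags and values must be 1-D arrays of equal length")
        object.__setattr__(self, "lags", lags)
        object.__setattr__(self, "values", values)

    @property
    def has_nan(self) -> bool:
        return bool(np.isnan(self.values).any())


def _times(train) -> np.ndarray:
    if isinstance(train, SpikeTrain):
        return train.times
    return np.asarray(train, dtype=np.float64)


def bin_spike_train(train: SpikeTrain, bin_size: float) -> BinnedTrain:
    """Count spikes in half-open bins [k*bin_size, (k+1)*bin_size).

    The number of bins is floor(length / bin_size); a spike at or beyond
    the last full bin edge is dropped.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be > 0")
    if bin_size > train.length:
        raise ValueError("bin_size exceeds recording length")
    n_bins = int(train.length // bin_size)
    idx = np.floor_divide(train.times, bin_size).astype(np.int64)
    idx = idx[idx < n_bins]
    counts = np.bincount(idx, minlength=n_bins)
    return BinnedTrain(counts=counts, bin_size=float(bin_size))


def bin_trials(trials: TrialSet, bin_size: float) -> np.ndarray:
    """Bin every trial identically; returns an (n_trials, n_bins) count matrix."""
    n_bins = int(trials.trial_duration // bin_size)
    if n_bins < 1:
        raise ValueError("bin_size exceeds trial duration")
    out = np.empty((trials.n_trials, n_bins), dtype=np.int64)
    for m, t in enumerate(trials.trials):
        idx = np.floor_divide(t, bin_size).astype(np.int64)
        idx = idx[idx < n_bins]
        out[m] = np.bincount(idx, minlength=n_bins)
    return out


def tiling_fraction(train, dt: float, total_length: float) -> float:
    """Fraction of [0, total_length] covered by the union of ±dt tiles.

    Overlapping tiles are merged and tiles are clipped to the signal
    window, so the result is a true proportion in [0, 1].  An empty train
    covers nothing.
    """
    times = _times(train)
    if total_length <= 0:
        raise ValueError("total_length must be > 0")
    if times.size == 0:
        return 0.0
    starts = np.clip(times - dt, 0.0, total_length)
    ends = np.clip(times + dt, 0.0, total_length)
    # sorted equal-width intervals: subtract each overlap with the previous tile
    covered = ends - np.maximum(starts, np.concatenate(([-np.inf], ends[:-1])))
    return float(np.sum(np.maximum(covered, 0.0)) / total_length)


def _p_fraction(a: np.ndarray, b: np.ndarray, dt: float) -> float:
    """Proportion of spikes in ``a`` lying within ±dt (inclusive) of any spike in ``b``."""
    lo = np.searchsorted(b, a - dt, side="left")
    hi = np.searchsorted(b, a + dt, side="right")
    return float(np.mean(hi > lo))


def _sttc_from_terms(pa: float, pb: float, ta: float, tb: float) -> float:
    """Assemble the two STTC half-terms; a vanishing denominator makes the
    value genuinely undefined and yields NaN."""
    den_a = 1.0 - pa * tb
    den_b = 1.0 - pb * ta
    half_a = (pa - tb) / den_a if den_a != 0.0 else np.nan
    half_b = (pb - ta) / den_b if den_b != 0.0 else np.nan
    return 0.5 * (half_a + half_b)


def sttc(a, b, dt: float, total_length: float) -> float:
    """Spike time tiling coefficient between two trains on [0, total_length].

    Returns NaN when either train is empty or a half-term denominator
    vanishes.  Symmetric in (a, b); bounded by [-1, 1] when finite.
    """
    ta_arr, tb_arr = _times(a), _times(b)
    if ta_arr.size == 0 or tb_arr.size == 0:
        return float("nan")
    pa = _p_fraction(ta_arr, tb_arr, dt)
    pb = _p_fraction(tb_arr, ta_arr, dt)
    t_a = tiling_fraction(ta_arr, dt, total_length)
    t_b = tiling_fraction(tb_arr, dt, total_length)
    return _sttc_from_terms(pa, pb, t_a, t_b)


def sttc_fixed_t(a, b, dt: float, t_a: float, t_b: float) -> float:
    """STTC with the tiling terms supplied by the caller.

    Used on zero-padded trial concatenations, where the T terms must come
    from the original trials (padding would otherwise dilute them); the P
    terms are unaffected by signal length and are computed from the trains.

    Unlike :func:`sttc`, an empty train here is an observed outcome ("no
    spikes in this window, in any trial") rather than an undefined
    comparison, so its P term takes the natural limit 0 instead of NaN;
    sparse trial sets therefore still yield finite curve values at large
    lags.
    """
    ta_arr, tb_arr = _times(a), _times(b)
    pa = _p_fraction(ta_arr, tb_arr, dt) if ta_arr.size and tb_arr.size else 0.0
    pb = _p_fraction(tb_arr, ta_arr, dt) if ta_arr.size and tb_arr.size else 0.0
    return _sttc_from_terms(pa, pb, t_a, t_b)


def acf_classic(binned: BinnedTrain, nlags: int) -> ACFCurve:
    """Classic spike-count autocorrelation.

        r(k) = sum_{t=k+1..N} (x_t - xbar)(x_{t-k} - xbar) / sum_t (x_t - xbar)^2

    with the unadjusted (full-series) denominator, so r(0) = 1.  A
    constant count series has no defined autocorrelation: all values NaN.
    """
    from statsmodels.tsa.stattools import acf as _sm_acf

    x = binned.counts.astype(np.float64)
    if x.size <= nlags:
        raise ValueError(f"need more than nlags={nlags} bins, got {x.size}")
    lags = np.arange(nlags + 1) * binned.bin_size
    if np.ptp(x) == 0:
        return ACFCurve(lags=lags, values=np.full(nlags + 1, np.nan), method="acf")
    values = _sm_acf(x, nlags=nlags, adjusted=False, fft=True)
    return ACFCurve(lags=lags, values=values, method="acf")


def isttc_acf(train: SpikeTrain, nlags: int, lag_shift: float, dt: float) -> ACFCurve:
    """Autocorrelation-like curve from STTC on lag-shifted copies of a train.

    For each lag k*lag_shift the train is compared with itself shifted back
    by the lag: spikes before length-lag form one train, spikes from lag
    onward (realigned by -lag) the other, and their STTC over the common
    window of length length-lag is the curve value.  Lag 0 is the
    self-STTC (1 for any nonempty train).  Lags where either truncated
    train is empty are NaN.
    """
    lags = np.arange(nlags + 1) * lag_shift
    if nlags * lag_shift >= train.length:
        raise ValueError("nlags * lag_shift must be smaller than the signal length")
    values = np.full(nlags + 1, np.nan)
    times = train.times
    if times.size == 0:
        return ACFCurve(lags=lags, values=values, method="isttc")
    values[0] = sttc(times, times, dt, train.length)
    for k in range(1, nlags + 1):
        lag = k * lag_shift
        a = times[times < train.length - lag]
        b = times[times >= lag] - lag
        if a.size and b.size:
            values[k] = sttc(a, b, dt, train.length - lag)
    return ACFCurve(lags=lags, values=values, method="isttc")


def pearsonr_trial_avg(trials_binned: np.ndarray, nlags: int,
                       bin_size: float) -> ACFCurve:
    """Trial-averaged Pearson autocorrelation of binned spike counts.

    Given a (n_trials, n_bins) count matrix, the across-trial Pearson
    correlation r_{i,j} is computed for every pair of the first ``nlags``
    bins, the diagonal is fixed at 1, and the curve value at lag k is the
    mean of the k-th superdiagonal.  Bins with zero across-trial variance
    produce NaN correlations; a lag is NaN only if its whole superdiagonal
    is NaN.  The curve has length ``nlags`` (lags 0 .. nlags-1 bins).
    """
    x = np.asarray(trials_binned, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2-D (n_trials >= 2, n_bins) count matrix")
    if x.shape[1] < nlags:
        raise ValueError(f"trials have {x.shape[1]} bins, need >= nlags={nlags}")
    sub = x[:, :nlags]
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(sub, rowvar=False)
    r = np.atleast_2d(r)
    np.fill_diagonal(r, 1.0)
    values = np.empty(nlags)
    for k in range(nlags):
        diag = np.diagonal(r, offset=k)
        finite = diag[np.isfinite(diag)]
        values[k] = finite.mean() if finite.size else np.nan
    lags = np.arange(nlags) * bin_size
    return ACFCurve(lags=lags, values=values, method="pearsonr")


def average_tiling(trials: TrialSet, effective_duration: float, dt: float) -> float:
    """Per-trial tiled fraction over [0, effective_duration], averaged across
    trials.  This is the fixed T term used on padded concatenations: it is
    computed inside each original trial, before padding, so the padding
    length cannot dilute it.  Empty trials contribute 0.
    """
    if effective_duration <= 0:
        raise ValueError("effective_duration must be > 0")
    return float(np.mean([tiling_fraction(t, dt, effective_duration)
                          for t in trials.trials]))


def concatenate_with_padding(trials: TrialSet, pad: float) -> SpikeTrain:
    """Lay trials end to end with a silent gap of ``pad`` ms after each one.

    Trial m's spikes are offset by m*(trial_duration + pad); with
    pad >= trial_duration no ±dt tile (dt < trial length) can bridge two
    trials, so the concatenation behaves like independent repeats.
    """
    if pad < trials.trial_duration:
        raise ValueError(
            f"pad ({pad} ms) must be >= trial duration ({trials.trial_duration} ms)"
        )
    step = trials.trial_duration + pad
    parts = [t + m * step for m, t in enumerate(trials.trials)]
    times = np.concatenate(parts) if parts else np.empty(0)
    return SpikeTrain(times=times, length=trials.n_trials * step)


def isttc_trials(trials: TrialSet, nlags: int, lag_shift: float, dt: float,
                 pad: float) -> ACFCurve:
    """iSTTC on epoched data: zero-padded concatenation with fixed T terms.

    For each lag, shifted ({t - lag | t >= lag}) and unshifted
    ({t | t < T_trial - lag}) segments are built per trial, concatenated
    with padding, and compared by STTC whose T terms are the per-trial
    tiled fractions over the effective duration T_trial - lag averaged
    across trials (never the padded length).  The result is invariant to
    the padding length for any pad >= trial duration.

    A lag at or beyond the trial duration leaves no data in either
    segment; such lags carry no information and are omitted from the
    curve (at the reference setting of 50 ms shifts on 1000 ms trials the
    last included lag is 950 ms, matching the length of the binned
    trial-averaged estimator).
    """
    if pad < trials.trial_duration:
        raise ValueError("pad must be >= trial duration")
    t_dur = trials.trial_duration
    n_valid = min(nlags, int(np.ceil(t_dur / lag_shift)) - 1)
    if n_valid < 1:
        raise ValueError("lag_shift must be smaller than the trial duration")
    lags = np.arange(n_valid + 1) * lag_shift
    values = np.full(n_valid + 1, np.nan)

    if trials.n_spikes:
        concat0 = concatenate_with_padding(trials, pad)
        t0 = average_tiling(trials, t_dur, dt)
        values[0] = sttc_fixed_t(concat0.times, concat0.times, dt, t0, t0)
        step = t_dur + pad
        for k in range(1, n_valid + 1):
            lag = k * lag_shift
            shifted = [t[t >= lag] - lag for t in trials.trials]
            unshifted = [t[t < t_dur - lag] for t in trials.trials]
            cat1 = np.concatenate([s + m * step for m, s in enumerate(shifted)])
            cat2 = np.concatenate([s + m * step for m, s in enumerate(unshifted)])
            eff = t_dur - lag
            t1 = float(np.mean([tiling_fraction(s, dt, eff) for s in shifted]))
            t2 = float(np.mean([tiling_fraction(s, dt, eff) for s in unshifted]))
            values[k] = sttc_fixed_t(cat1, cat2, dt, t1, t2)
    return ACFCurve(lags=lags, values=values, method="isttc_trials")
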