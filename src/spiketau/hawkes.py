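"""Hawkes-process spike-train simulation with known intrinsic timescales.

A univariate self-exciting Hawkes process with an exponential kernel produces
spike trains whose spike-count autocorrelation decays exponentially with a
known time constant, making it the standard ground-truth generator for
benchmarking intrinsic-timescale estimators.

The conditional intensity is

    lambda(t) = mu + sum_{t_i < t} (alpha / tau_kernel) * exp(-(t - t_i) / tau_kernel)

with baseline ``mu`` (events/ms here), excitation strength ``alpha`` in
[0, 1) (total integrated excitation per spike; ``alpha >= 1`` makes the
process explode) and kernel time constant ``tau_kernel`` (ms).  The
stationary rate is ``mu / (1 - alpha)`` and the autocorrelation time
constant is ``tau_kernel / (1 - alpha)``.  Choosing

    mu = f * (1 - alpha)        tau_kernel = tau * (1 - alpha)

therefore yields a train with stationary rate ``f`` and ground-truth
intrinsic timescale ``tau``.

All times are in milliseconds; rates are supplied in Hz and converted
internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HawkesParams",
    "SpikeTrain",
    "TrialSet",
    "derive_kernel_params",
    "simulate_hawkes",
    "generate_parametric_dataset",
    "extract_pseudo_trials",
    "truncate_signal",
    "theoretical_acf",
    "PARAMETRIC_RANGES",
]

#: Default parameter ranges of the parametric benchmark grid:
#: firing rate (Hz), excitation strength, intrinsic timescale (ms),
#: and signal duration (ms).
PARAMETRIC_RANGES = {
    "f_range": (0.01, 10.0),
    "alpha_range": (0.1, 0.9),
    "tau_range": (50.0, 300.0),
    "duration": 600_000.0,
}

#: Hard cap on events per simulated unit; exceeded only for near-critical
#: alpha at high rates, where the simulation would otherwise run away.
DEFAULT_MAX_EVENTS = 10_000_000


@dataclass(frozen=True)
class HawkesParams:
    """Target parameters of one simulated unit.

    Attributes
    ----------
    rate : float
        Target stationary firing rate ``f`` in Hz.
    tau : float
        Ground-truth intrinsic timescale in ms (autocorrelation decay
        constant of the resulting train).
    alpha : float
        Excitation strength in [0, 1).
    duration : float
        Total simulated time in ms.
    seed : int
        Seed of the per-unit random generator.
    """

    rate: float
    tau: float
    alpha: float
    duration: float
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha < 1.0):
            raise ValueError(
                f"alpha must be in [0, 1) for a stationary process, got {self.alpha}"
            )
        if self.rate <= 0:
            raise ValueError(f"rate must be > 0, got {self.rate}")
        if self.tau <= 0:
            raise ValueError(f"tau must be > 0, got {self.tau}")
        if self.duration <= 0:
            raise ValueError(f"duration must be > 0, got {self.duration}")


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike times (ms) on a recording of known length (ms)."""

    times: np.ndarray
    length: float

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=np.float64)
        object.__setattr__(self, "times", times)
        if times.ndim != 1:
            raise ValueError("spike times must be a 1-D array")
        if self.length <= 0:
            raise ValueError(f"length must be > 0, got {self.length}")
        if times.size:
            if np.any(np.diff(times) <= 0):
                raise ValueError("spike times must be strictly increasing")
            if times[0] < 0 or times[-1] >= self.length:
                raise ValueError("spike times must lie in [0, length)")

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    @property
    def isis(self) -> np.ndarray:
        """Inter-spike intervals, ms."""
        return np.diff(self.times)

    @property
    def firing_rate(self) -> float:
        """Empirical rate in Hz."""
        return self.n_spikes / self.length * 1000.0


@dataclass(frozen=True)
class TrialSet:
    """Equal-duration trials of spike times, each re-referenced to trial start."""

    trials: tuple
    trial_duration: float

    def __post_init__(self) -> None:
        if self.trial_duration <= 0:
            raise ValueError("trial_duration must be > 0")
        trials = tuple(np.asarray(t, dtype=np.float64) for t in self.trials)
        if not trials:
            raise ValueError("TrialSet needs at least one trial")
        for t in trials:
            if t.size and (np.any(np.diff(t) < 0) or t[0] < 0 or t[-1] >= self.trial_duration):
                raise ValueError("trial spike times must be sorted within [0, trial_duration)")
        object.__setattr__(self, "trials", trials)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_spikes(self) -> int:
        return int(sum(t.size for t in self.trials))


def derive_kernel_params(rate: float, tau: float, alpha: float) -> tuple[float, float]:
    """Map target (rate, tau, alpha) to Hawkes (mu, tau_kernel).

    Parameters
    ----------
    rate : float
        Target stationary rate f, Hz.
    tau : float
        Target autocorrelation time constant, ms.
    alpha : float
        Excitation strength in [0, 1).

    Returns
    -------
    (mu, tau_kernel)
        Baseline intensity in Hz and kernel time constant in ms such that
        the stationary rate is ``rate`` and the autocorrelation decay
        constant is ``tau``.
    """
    if not (0.0 <= alpha < 1.0):
        raise ValueError(f"alpha must be in [0, 1), got {alpha}")
    if rate <= 0 or tau <= 0:
        raise ValueError("rate and tau must be > 0")
    return rate * (1.0 - alpha), tau * (1.0 - alpha)


class _UniformBuffer:
    """Block-buffered uniforms: scalar draws from a Generator are slow,
    refilling in blocks keeps the thinning loop cheap."""

    __slots__ = ("_rng", "_block", "_buf", "_i")

    def __init__(self, rng: np.random.Generator, block: int = 1 << 14):
        self._rng = rng
        self._block = block
        self._buf = rng.random(block)
        self._i = 0

    def next(self) -> float:
        i = self._i
        if i >= self._block:
            self._buf = self._rng.random(self._block)
            i = 0
        self._i = i + 1
        return self._buf[i]


def simulate_hawkes(
    params: HawkesParams,
    max_events: int = DEFAULT_MAX_EVENTS,
    rng: np.random.Generator | None = None,
) -> SpikeTrain:
    """Simulate one unit by Ogata's thinning algorithm.

    The excitation part of the intensity is maintained recursively: for an
    exponential kernel the intensity only decays between events, so the
    post-event intensity is a valid dominating bound.  A candidate waiting
    time is drawn from an exponential with the current bound and accepted
    with probability lambda(candidate)/bound; on rejection the (decayed)
    intensity at the candidate becomes the new bound.

    Parameters
    ----------
    params : HawkesParams
        Target rate/timescale/excitation/duration and per-unit seed.
    max_events : int
        Guard against runaway event counts; a RuntimeError is raised when
        exceeded.
    rng : numpy Generator, optional
        Overrides the seed-derived generator (used by the dataset driver).
    """
    mu_hz, tau_kernel = derive_kernel_params(params.rate, params.tau, params.alpha)
    mu = mu_hz / 1000.0  # events per ms
    if rng is None:
        rng = np.random.default_rng(params.seed)

    duration = params.duration
    uni = _UniformBuffer(rng)
    events: list[float] = []
    append = events.append
    exp = math.exp
    log = math.log

    if params.alpha == 0.0:
        # Poisson limit: no excitation, draw the whole train vectorized.
        n = rng.poisson(mu * duration)
        if n > max_events:
            raise RuntimeError(f"event cap exceeded: {n} > {max_events}")
        times = np.sort(rng.uniform(0.0, duration, size=n))
        times = times[np.concatenate(([True], np.diff(times) > 0))] if n else times
        return SpikeTrain(times=times, length=duration)

    eta = params.alpha / tau_kernel  # intensity jump per event, per ms
    inv_tauk = 1.0 / tau_kernel
    t = 0.0
    excitation = 0.0  # sum of decayed kernel contributions at current time
    while True:
        bound = mu + excitation
        w = -log(1.0 - uni.next()) / bound
        t += w
        if t >= duration:
            break
        excitation *= exp(-w * inv_tauk)
        lam = mu + excitation
        if uni.next() * bound <= lam:
            append(t)
            if len(events) > max_events:
                raise RuntimeError(
                    f"event cap exceeded: more than {max_events} events "
                    f"(rate={params.rate} Hz, alpha={params.alpha})"
                )
            excitation += eta
    return SpikeTrain(times=np.asarray(events, dtype=np.float64), length=duration)


def generate_parametric_dataset(
    n_units: int,
    f_range: tuple[float, float] = PARAMETRIC_RANGES["f_range"],
    tau_range: tuple[float, float] = PARAMETRIC_RANGES["tau_range"],
    alpha_range: tuple[float, float] = PARAMETRIC_RANGES["alpha_range"],
    duration: float = PARAMETRIC_RANGES["duration"],
    seed: int = 0,
    max_events: int = DEFAULT_MAX_EVENTS,
) -> list[tuple[HawkesParams, SpikeTrain]]:
    """Draw ``n_units`` parameter sets uniformly within the given ranges and
    simulate each one.

    A dataset-level generator draws the parameters and spawns one integer
    seed per unit, so per-unit simulations are independently reproducible.
    """
    for name, (lo, hi) in (("f_range", f_range), ("tau_range", tau_range), ("alpha_range", alpha_range)):
        if not (lo <= hi):
            raise ValueError(f"{name} is inverted: {(lo, hi)}")
    if n_units < 1:
        raise ValueError("n_units must be >= 1")

    root = np.random.default_rng(seed)
    fs = root.uniform(*f_range, size=n_units)
    taus = root.uniform(*tau_range, size=n_units)
    alphas = root.uniform(*alpha_range, size=n_units)
    unit_seeds = root.integers(0, 2**31 - 1, size=n_units)

    out = []
    for f, tau, alpha, s in zip(fs, taus, alphas, unit_seeds):
        p = HawkesParams(rate=float(f), tau=float(tau), alpha=float(alpha),
                         duration=float(duration), seed=int(s))
        out.append((p, simulate_hawkes(p, max_events=max_events)))
    return out


def extract_pseudo_trials(
    train: SpikeTrain,
    n_trials: int,
    trial_len: float,
    seed: int = 0,
    allow_overlap: bool = False,
    max_attempts_per_trial: int = 10_000,
) -> TrialSet:
    """Cut random fixed-length windows out of a continuous recording.

    Emulates trial-based (epoched) data by sampling ``n_trials`` windows of
    ``trial_len`` ms from the recording; spike times are re-referenced to
    each window's start.  By default windows are non-overlapping (placed by
    rejection sampling of start times) so no spike is counted twice;
    ``allow_overlap=True`` lifts that constraint.
    """
    if n_trials < 1 or trial_len <= 0:
        raise ValueError("n_trials >= 1 and trial_len > 0 required")
    if trial_len > train.length:
        raise ValueError("trial_len exceeds recording length")
    if not allow_overlap and n_trials * trial_len > train.length:
        raise ValueError(
            f"cannot place {n_trials} non-overlapping windows of {trial_len} ms "
            f"in a {train.length} ms recording"
        )
    rng = np.random.default_rng(seed)
    hi = train.length - trial_len
    starts: list[float] = []
    attempts = 0
    budget = max_attempts_per_trial * n_trials
    while len(starts) < n_trials:
        s = rng.uniform(0.0, hi)
        attempts += 1
        if allow_overlap or all(abs(s - s0) >= trial_len for s0 in starts):
            starts.append(s)
        elif attempts > budget:
            raise RuntimeError(
                "could not place non-overlapping pseudo-trials; recording too "
                "densely packed (try allow_overlap=True)"
            )
    times = train.times
    trials = []
    for s in starts:
        lo_i, hi_i = np.searchsorted(times, [s, s + trial_len])
        trials.append(times[lo_i:hi_i] - s)
    return TrialSet(trials=tuple(trials), trial_duration=float(trial_len))


def truncate_signal(train: SpikeTrain, new_length: float) -> SpikeTrain:
    """Shorten a recording to ``new_length`` ms, dropping later spikes."""
    if not (0 < new_length <= train.length):
        raise ValueError(f"new_length must be in (0, {train.length}], got {new_length}")
    keep = np.searchsorted(train.times, new_length, side="left")
    return SpikeTrain(times=train.times[:keep], length=float(new_length))


def theoretical_acf(tau: float, lags: np.ndarray) -> np.ndarray:
    """Unit-amplitude exponential autocorrelation exp(-|lag|/tau)."""
    if tau <= 0:
        raise ValueError("tau must be > 0")
    return np.exp(-np.abs(np.asarray(lags, dtype=np.float64)) / tau)
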