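"""End-to-end benchmark orchestration.

Runs the full study loop on simulated units: Hawkes simulation with known
ground-truth timescales, optional pseudo-trial extraction, the four
curve estimators, exponential fitting with confidence intervals, QC
flags, and relative estimation errors — then aggregates per-method
accuracy, pass rates and rejection rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import estimators as est
from .estimators import STTCConfig
from .fitting import fit_exponential
from .hawkes import (PARAMETRIC_RANGES, HawkesParams, SpikeTrain,
                     extract_pseudo_trials, generate_parametric_dataset)
from .qc import local_variation, qc_report, relative_estimation_error

__all__ = ["BenchmarkConfig", "ALL_METHODS", "estimate_curve", "analyze_unit",
           "run_benchmark", "summarize_benchmark", "resample_trials_stability"]

ALL_METHODS = ("acf", "isttc", "pearsonr", "isttc_trials")
TRIAL_METHODS = ("pearsonr", "isttc_trials")
REE_INTERVALS = (100.0, 75.0, 50.0, 25.0)


@dataclass(frozen=True)
class BenchmarkConfig:
    """Everything needed to reproduce one benchmark run."""

    n_units: int = 100
    f_range: tuple[float, float] = PARAMETRIC_RANGES["f_range"]
    tau_range: tuple[float, float] = PARAMETRIC_RANGES["tau_range"]
    alpha_range: tuple[float, float] = PARAMETRIC_RANGES["alpha_range"]
    duration: float = PARAMETRIC_RANGES["duration"]
    seed: int = 0
    n_trials: int = 40
    trial_len: float = 1000.0
    estimator: STTCConfig = field(default_factory=STTCConfig.default)
    fit_start_lag: int = 1
    ci_level: float = 0.95
    methods: tuple[str, ...] = ALL_METHODS

    def __post_init__(self) -> None:
        bad = set(self.methods) - set(ALL_METHODS)
        if bad:
            raise ValueError(f"unknown methods: {sorted(bad)}")


def estimate_curve(method: str, cfg: STTCConfig, train: SpikeTrain | None = None,
                   trials=None) -> est.ACFCurve:
    """Dispatch one estimator by name with shared hyperparameters."""
    if method == "acf":
        return est.acf_classic(est.bin_spike_train(train, cfg.bin_size), cfg.nlags)
    if method == "isttc":
        return est.isttc_acf(train, cfg.nlags, cfg.lag_shift, cfg.dt)
    if method == "pearsonr":
        mat = est.bin_trials(trials, cfg.bin_size)
        return est.pearsonr_trial_avg(mat, cfg.nlags, cfg.bin_size)
    if method == "isttc_trials":
        return est.isttc_trials(trials, cfg.nlags, cfg.lag_shift, cfg.dt, cfg.pad)
    raise ValueError(f"unknown method {method!r}")


def analyze_unit(unit_id, params: HawkesParams, train: SpikeTrain,
                 config: BenchmarkConfig, trial_seed: int) -> list[dict]:
    """Run every requested method on one unit; failures become rows with a
    failure status instead of aborting the run."""
    cfg = config.estimator
    lv = local_variation(train)
    trials = None
    if any(m in TRIAL_METHODS for m in config.methods):
        trials = extract_pseudo_trials(train, config.n_trials, config.trial_len,
                                       seed=trial_seed)
    rows = []
    for method in config.methods:
        base = {
            "unit_id": unit_id, "method": method,
            "f": params.rate, "tau_gt": params.tau, "alpha": params.alpha,
            "duration_ms": params.duration, "lv": lv,
            "firing_rate": train.firing_rate,
        }
        try:
            curve = estimate_curve(method, cfg, train=train, trials=trials)
            fit = fit_exponential(curve, config.fit_start_lag, config.ci_level)
            qc = qc_report(fit, curve)
        except Exception as exc:  # per-unit robustness: record, don't abort
            rows.append({**base, "tau_est": np.nan, "ree_pct": np.nan,
                         "status": "fit_failed", "rejected": True,
                         "rejection_reason": "fit_failed",
                         "error": type(exc).__name__})
            continue
        tau_est = fit.tau if fit.ok else np.nan
        ci_lo, ci_hi = (fit.ci[1], fit.ci[2]) if fit.ci else (np.nan, np.nan)
        rows.append({
            **base,
            "a": fit.amplitude, "b": fit.decay_rate, "c": fit.offset,
            "tau_est": tau_est, "sigma_tau": fit.sigma_tau,
            "ci_low": ci_lo, "ci_high": ci_hi,
            "r_squared": fit.r_squared, "n_points": fit.n_points,
            "status": fit.status,
            "ree_pct": relative_estimation_error(tau_est, params.tau),
            "declines_50_200": qc.declines_50_200,
            "ci_excludes_zero": qc.ci_excludes_zero,
            "r2_pass": qc.r2_pass,
            "rejected": qc.rejected,
            "rejection_reason": qc.rejection_reason,
            "error": "",
        })
    return rows


def run_benchmark(config: BenchmarkConfig,
                  dataset: list[tuple[HawkesParams, SpikeTrain]] | None = None
                  ) -> pd.DataFrame:
    """Simulate (or reuse) a dataset and produce one fit row per unit and
    method, ordered by unit id.  Deterministic given the config seeds."""
    if dataset is None:
        dataset = generate_parametric_dataset(
            config.n_units, config.f_range, config.tau_range,
            config.alpha_range, config.duration, seed=config.seed)
    trial_seeds = np.random.default_rng(config.seed + 1).integers(
        0, 2**31 - 1, size=len(dataset))
    rows = []
    for uid, ((params, train), ts) in enumerate(zip(dataset, trial_seeds)):
        rows.extend(analyze_unit(uid, params, train, config, int(ts)))
    return pd.DataFrame(rows)


def summarize_benchmark(fits: pd.DataFrame) -> pd.DataFrame:
    """Per-method accuracy and inclusion summary.

    Reports the median absolute REE, the fraction of units with |REE|
    within 100/75/50/25%, rejection rates (total and by reason), and the
    pass rate of each QC criterion.  Fractions are over all units of the
    method, so a rejected unit counts as outside every REE interval.
    """
    if fits.empty:
        raise ValueError("no benchmark records to summarize")
    out = []
    for method, grp in fits.groupby("method", sort=True):
        n = len(grp)
        abs_ree = grp["ree_pct"].abs()
        row = {
            "method": method, "n_units": n,
            "median_abs_ree": float(abs_ree.median()),
            "rejection_rate": float(grp["rejected"].mean()),
            "rate_fit_failed": float((grp["rejection_reason"] == "fit_failed").mean()),
            "rate_negative_r2": float((grp["rejection_reason"] == "negative_r2").mean()),
            "pass_decline": float((grp["declines_50_200"] == True).mean())  # noqa: E712
            if "declines_50_200" in grp else np.nan,
            "pass_ci_excl_zero": float((grp["ci_excludes_zero"] == True).mean())  # noqa: E712
            if "ci_excludes_zero" in grp else np.nan,
            "pass_r2": float((grp["r2_pass"] == True).mean())  # noqa: E712
            if "r2_pass" in grp else np.nan,
        }
        for w in REE_INTERVALS:
            row[f"frac_within_{int(w)}"] = float((abs_ree <= w).mean())
        out.append(row)
    return pd.DataFrame(out)


def resample_trials_stability(train: SpikeTrain, n_iterations: int,
                              n_trials: int = 40, trial_len: float = 1000.0,
                              estimator: STTCConfig | None = None,
                              fit_start_lag: int = 1, seed: int = 0,
                              methods: tuple[str, ...] = TRIAL_METHODS,
                              within_pct: tuple[float, ...] = (10.0, 25.0, 50.0),
                              n_boot: int = 200) -> pd.DataFrame:
    """Stability of trial-based estimates under repeated trial resampling.

    Extracts a fresh random trial set ``n_iterations`` times, re-estimates
    tau per method each time, and reports the median estimate, a bootstrap
    standard error of the median across iterations, and the fraction of
    estimates within fixed percentage ranges of the median.
    """
    cfg = estimator or STTCConfig.default()
    iter_seeds = np.random.default_rng(seed).integers(0, 2**31 - 1,
                                                      size=n_iterations)
    taus: dict[str, list[float]] = {m: [] for m in methods}
    for s in iter_seeds:
        trials = extract_pseudo_trials(train, n_trials, trial_len, seed=int(s))
        for m in methods:
            curve = estimate_curve(m, cfg, trials=trials)
            fit = fit_exponential(curve, fit_start_lag)
            taus[m].append(fit.tau if fit.ok else np.nan)
    boot_rng = np.random.default_rng(seed + 1)
    rows = []
    for m in methods:
        vals = np.asarray(taus[m])
        finite = vals[np.isfinite(vals)]
        med = float(np.median(finite)) if finite.size else np.nan
        if finite.size >= 2:
            idx = boot_rng.integers(0, finite.size, size=(n_boot, finite.size))
            se = float(np.std(np.median(finite[idx], axis=1), ddof=1))
        else:
            se = np.nan
        row = {"method": m, "n_iterations": n_iterations,
               "n_estimates": int(finite.size), "median_tau": med,
               "se_median": se}
        for w in within_pct:
            row[f"frac_within_{int(w)}pct"] = (
                float(np.mean(np.abs(finite - med) <= w / 100.0 * med))
                if finite.size and med == med else np.nan)
        rows.append(row)
    return pd.DataFrame(rows)
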