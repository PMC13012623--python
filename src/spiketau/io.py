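"""Plain-text table formats for spike trains, trials, curves and fits.

Everything is delimiter-separated text read and written through pandas:

* spike-train file: columns ``unit_id, spike_time_ms``, sorted within
  unit, with a sidecar JSON (``<file>.meta.json``) recording each unit's
  recording length in ms;
* trial file: adds a ``trial_index`` column; the sidecar records
  ``trial_duration_ms`` and ``n_trials``;
* curve file: ``unit_id, method, lag_ms, value``;
* fit/benchmark tables: one row per unit and method (see
  :mod:`spiketau.pipeline`).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .estimators import ACFCurve
from .hawkes import SpikeTrain, TrialSet

__all__ = [
    "write_spike_trains", "read_spike_trains",
    "write_trials", "read_trials",
    "write_curves", "read_curves",
]


def _meta_path(path) -> Path:
    return Path(str(path) + ".meta.json")


def write_spike_trains(path, trains: dict[str, SpikeTrain]) -> None:
    """Write ``{unit_id: SpikeTrain}`` to CSV plus a sidecar with lengths."""
    rows = []
    meta = {}
    for uid, tr in trains.items():
        rows.append(pd.DataFrame({"unit_id": uid, "spike_time_ms": tr.times}))
        meta[str(uid)] = {"length_ms": tr.length}
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)
    _meta_path(path).write_text(json.dumps(meta, indent=1))


def read_spike_trains(path, length_ms: float | None = None) -> dict[str, SpikeTrain]:
    """Read a spike-train CSV; lengths come from the sidecar unless given."""
    df = pd.read_csv(path)
    meta = {}
    mp = _meta_path(path)
    if mp.exists():
        meta = json.loads(mp.read_text())
    out = {}
    for uid, grp in df.groupby("unit_id", sort=True):
        length = meta.get(str(uid), {}).get("length_ms", length_ms)
        if length is None:
            raise ValueError(f"no recording length for unit {uid}: "
                             "provide length_ms or a sidecar metadata file")
        out[str(uid)] = SpikeTrain(times=np.sort(grp["spike_time_ms"].to_numpy()),
                                   length=float(length))
    return out


def write_trials(path, trialsets: dict[str, TrialSet]) -> None:
    """Write ``{unit_id: TrialSet}`` to CSV with a trial_index column."""
    rows = []
    meta = {}
    for uid, ts in trialsets.items():
        for m, t in enumerate(ts.trials):
            rows.append(pd.DataFrame({"unit_id": uid, "trial_index": m,
                                      "spike_time_ms": t}))
        meta[str(uid)] = {"trial_duration_ms": ts.trial_duration,
                          "n_trials": ts.n_trials}
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)
    _meta_path(path).write_text(json.dumps(meta, indent=1))


def read_trials(path) -> dict[str, TrialSet]:
    df = pd.read_csv(path)
    meta = json.loads(_meta_path(path).read_text())
    out = {}
    for uid, grp in df.groupby("unit_id", sort=True):
        m = meta[str(uid)]
        trials = []
        for i in range(int(m["n_trials"])):
            t = grp.loc[grp["trial_index"] == i, "spike_time_ms"].to_numpy()
            trials.append(np.sort(t))
        out[str(uid)] = TrialSet(trials=tuple(trials),
                                 trial_duration=float(m["trial_duration_ms"]))
    return out


def write_curves(path, curves: dict[str, ACFCurve] | list[tuple[str, ACFCurve]]) -> None:
    """Write curves as long-format CSV: unit_id, method, lag_ms, value."""
    items = curves.items() if isinstance(curves, dict) else curves
    rows = [pd.DataFrame({"unit_id": uid, "method": c.method,
                          "lag_ms": c.lags, "value": c.values})
            for uid, c in items]
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_curves(path) -> list[tuple[str, ACFCurve]]:
    df = pd.read_csv(path)
    out = []
    for (uid, method), grp in df.groupby(["unit_id", "method"], sort=True):
        grp = grp.sort_values("lag_ms")
        out.append((str(uid), ACFCurve(lags=grp["lag_ms"].to_numpy(),
                                       values=grp["value"].to_numpy(),
                                       method=str(method))))
    return out
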