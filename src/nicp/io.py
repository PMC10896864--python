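"""Session and observation file I/O.

Sessions are plain CSV with header ``time,ppg_distal[,ppg_proximal],icp``,
time in seconds on a uniform grid. Observation tables are CSV with one row
per 60-s window. Both round-trip losslessly at text precision.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import FEATURE_NAMES, Dataset, SampledSignal, SessionRecording, WindowObservation

__all__ = ["read_session", "write_session", "read_observations", "write_observations"]

_REQUIRED_COLUMNS = ("time", "ppg_distal", "icp")
_RATE_TOL = 0.01  # relative tolerance on the sampling rate


def read_session(path: str | Path, rate: float = 100.0, patient_id: str | None = None) -> SessionRecording:
    """Read one patient session from CSV.

    Requires columns ``time``, ``ppg_distal`` and ``icp`` (``ppg_proximal``
    optional); time must be monotone at a fixed step matching ``1/rate``
    within 1%.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        raise ValueError(f"{path}: empty session file")
    for col in _REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    t = df["time"].to_numpy(dtype=np.float64)
    if t.size > 1:
        dt = np.diff(t)
        step = 1.0 / rate
        if np.any(dt <= 0) or np.any(np.abs(dt - step) > _RATE_TOL * step):
            raise ValueError(f"{path}: non-uniform sampling (expected fixed step {step:g} s)")
    t0 = float(t[0])
    proximal = None
    if "ppg_proximal" in df.columns:
        proximal = SampledSignal(df["ppg_proximal"].to_numpy(np.float64), rate, t0)
    return SessionRecording(
        patient_id=patient_id or path.stem,
        ppg_distal=SampledSignal(df["ppg_distal"].to_numpy(np.float64), rate, t0),
        icp=SampledSignal(df["icp"].to_numpy(np.float64), rate, t0),
        ppg_proximal=proximal,
    )


def write_session(rec: SessionRecording, path: str | Path) -> None:
    cols = {
        "time": rec.ppg_distal.times(),
        "ppg_distal": rec.ppg_distal.values,
    }
    if rec.ppg_proximal is not None:
        cols["ppg_proximal"] = rec.ppg_proximal.values
    cols["icp"] = rec.icp.values
    pd.DataFrame(cols).to_csv(path, index=False)


def write_observations(obs: list[WindowObservation] | Dataset, path: str | Path) -> None:
    """Write window observations (optionally with split labels) to CSV."""
    ds = obs if isinstance(obs, Dataset) else Dataset(list(obs))
    if not len(ds):
        raise ValueError("refusing to write an empty observation table")
    ds.to_frame().to_csv(path, index=False)


def read_observations(path: str | Path) -> Dataset:
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        raise ValueError(f"{path}: empty observation table")
    missing = set(("patient_id", "window_index", "mean_icp_mmhg", "n_pulses") + FEATURE_NAMES) - set(
        df.columns
    )
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return Dataset.from_frame(df)
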