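"""Domain types shared across the pipeline.

The carriers here are deliberately plain: a uniformly sampled signal, a
patient session of aligned signals, a 60-s window observation (11 pulse
morphology features + mean invasive ICP), and a split dataset of such
observations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd

__all__ = [
    "FEATURE_NAMES",
    "SampledSignal",
    "SessionRecording",
    "WindowObservation",
    "Dataset",
]

#: Canonical order of the 11 pulse-morphology features.
FEATURE_NAMES: tuple[str, ...] = (
    "amplitude",
    "pulse_width_s",
    "rise_time_s",
    "decay_time_s",
    "upslope_per_s",
    "downslope_per_s",
    "auc",
    "sys_area",
    "dia_area",
    "sys_dia_ratio",
    "sdppg_ratio",
)

#: Guard range for plausible invasive ICP samples (mmHg).
ICP_GUARD_MMHG = (-10.0, 100.0)


@dataclass
class SampledSignal:
    """A uniformly sampled series.

    ``values`` are arbitrary units for PPG and mmHg for ICP; ``rate`` is the
    sampling frequency in Hz and ``t0`` the start-time offset in seconds.
    """

    values: np.ndarray
    rate: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValueError("SampledSignal values must be one-dimensional")
        if not self.rate > 0:
            raise ValueError("sampling rate must be positive")

    def __len__(self) -> int:
        return self.values.size

    @property
    def duration_s(self) -> float:
        return self.values.size / self.rate

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.rate

    def slice(self, start: int, stop: int) -> "SampledSignal":
        """Contiguous sub-signal ``[start, stop)`` with an adjusted ``t0``."""
        return SampledSignal(self.values[start:stop], self.rate, self.t0 + start / self.rate)


@dataclass
class SessionRecording:
    """One patient's time-synchronized recording.

    Distal (cerebral) PPG, optional proximal (extracerebral) PPG, and the
    invasive ICP reference, all sampled on the same grid.
    """

    patient_id: str
    ppg_distal: SampledSignal
    icp: SampledSignal
    ppg_proximal: SampledSignal | None = None

    def __post_init__(self) -> None:
        signals = [self.ppg_distal, self.icp]
        if self.ppg_proximal is not None:
            signals.append(self.ppg_proximal)
        rates = {s.rate for s in signals}
        lengths = {len(s) for s in signals}
        if len(rates) != 1:
            raise ValueError(f"signals of session {self.patient_id!r} have mixed rates {rates}")
        if len(lengths) != 1:
            raise ValueError(
                f"signals of session {self.patient_id!r} have mixed lengths {lengths}"
            )
        finite = self.icp.values[np.isfinite(self.icp.values)]
        if finite.size and (finite.min() < ICP_GUARD_MMHG[0] or finite.max() > ICP_GUARD_MMHG[1]):
            raise ValueError(
                f"ICP samples outside the physiologic guard range {ICP_GUARD_MMHG} mmHg"
            )

    @property
    def rate(self) -> float:
        return self.ppg_distal.rate

    def __len__(self) -> int:
        return len(self.ppg_distal)


@dataclass
class WindowObservation:
    """One 60-s window: median pulse features paired with mean invasive ICP."""

    patient_id: str
    window_index: int
    features: dict[str, float]
    mean_icp_mmhg: float
    n_pulses: int

    def __post_init__(self) -> None:
        missing = set(FEATURE_NAMES) - set(self.features)
        if missing:
            raise ValueError(f"missing features: {sorted(missing)}")

    def feature_array(self) -> np.ndarray:
        return np.array([self.features[name] for name in FEATURE_NAMES], dtype=np.float64)


SPLIT_LABELS = ("train", "val", "test")


@dataclass
class Dataset:
    """Window observations plus a train/val/test partition label each."""

    observations: list[WindowObservation]
    split: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.split and len(self.split) != len(self.observations):
            raise ValueError("split labels must match observations one-to-one")
        bad = set(self.split) - set(SPLIT_LABELS)
        if bad:
            raise ValueError(f"unknown split labels {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.observations)

    def subset(self, label: str) -> "Dataset":
        if label not in SPLIT_LABELS:
            raise ValueError(f"unknown split label {label!r}")
        obs = [o for o, s in zip(self.observations, self.split) if s == label]
        return Dataset(obs, [label] * len(obs))

    def matrices(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Feature matrix (n, 11), ICP target (n,), patient id array (n,)."""
        if not self.observations:
            return (
                np.empty((0, len(FEATURE_NAMES))),
                np.empty(0),
                np.empty(0, dtype=object),
            )
        X = np.stack([o.feature_array() for o in self.observations])
        y = np.array([o.mean_icp_mmhg for o in self.observations])
        pid = np.array([o.patient_id for o in self.observations], dtype=object)
        return X, y, pid

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, o in enumerate(self.observations):
            row = {"patient_id": o.patient_id, "window_index": o.window_index}
            row.update({name: o.features[name] for name in FEATURE_NAMES})
            row["mean_icp_mmhg"] = o.mean_icp_mmhg
            row["n_pulses"] = o.n_pulses
            if self.split:
                row["split"] = self.split[i]
            rows.append(row)
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Dataset":
        obs = []
        for _, row in df.iterrows():
            obs.append(
                WindowObservation(
                    patient_id=str(row["patient_id"]),
                    window_index=int(row["window_index"]),
                    features={name: float(row[name]) for name in FEATURE_NAMES},
                    mean_icp_mmhg=float(row["mean_icp_mmhg"]),
                    n_pulses=int(row["n_pulses"]),
                )
            )
        split = [str(s) for s in df["split"]] if "split" in df.columns else []
        return cls(obs, split)
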