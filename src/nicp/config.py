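"""Analysis configuration.

All fixed constants of the estimation pipeline live here: filter corners for
the AC/DC decomposition, the AC/DC normalization factor, windowing and
inclusion rules, the stratified-split fractions, the ensemble hyperparameters
and the evaluation thresholds. Defaults are the study constants; a YAML file
or keyword overrides may change them, and invalid combinations are rejected
eagerly so downstream code can assume a coherent configuration.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import yaml

__all__ = ["AnalysisConfig", "load_config"]


@dataclass
class AnalysisConfig:
    """Pipeline constants.

    Parameters
    ----------
    ac_band_hz : (float, float)
        Butterworth bandpass corners isolating the cardiac (AC) component.
    dc_cut_hz : float
        Lowpass corner isolating the slowly varying baseline (DC) component.
    filter_order : int
        Order of both Butterworth designs (applied zero-phase, so the
        effective attenuation is squared).
    norm_factor : float
        Multiplier in the perfusion-style normalization ``norm_factor*AC/DC``.
    window_s : float
        Observation window length in seconds; per-pulse features are reduced
        to their median and invasive ICP to its mean over each window.
    icp_min_mmhg, icp_max_mmhg : float
        Inclusion range for window mean ICP (mmHg).
    bin_width_mmhg : float
        Width of the ICP strata used for the train/val/test partition.
    test_fraction : float
        Fraction of each stratum assigned to the test set.
    val_fraction_of_train : float
        Fraction of the non-test remainder held out for validation.
    n_trees, max_depth, min_leaf : int
        Bagged-ensemble size, per-tree depth cap (edges from the root) and
        minimum samples per leaf.
    hypertension_threshold_mmhg : float
        Intracranial-hypertension cut-off for the ROC analysis (mmHg).
    loa_z : float
        Z multiplier for the Bland-Altman limits of agreement.
    min_pulses_per_window : int
        Windows with fewer accepted pulses are dropped.
    rng_seed : int
        Single seed from which all pipeline randomness flows.
    hr_bounds_bpm : (float, float)
        Plausible adult heart-rate range; pulses outside are rejected.
    saturation_margin : float
        Rail proximity (fraction of the observed signal span) that counts as
        photodetector saturation.
    artifact_z : float
        Robust z-score threshold on windowed peak-to-peak amplitude for
        movement-artifact detection.
    """

    ac_band_hz: tuple[float, float] = (0.8, 10.0)
    dc_cut_hz: float = 0.1
    filter_order: int = 2
    norm_factor: float = 10.0
    window_s: float = 60.0
    icp_min_mmhg: float = 5.0
    icp_max_mmhg: float = 40.0
    bin_width_mmhg: float = 5.0
    test_fraction: float = 0.2
    val_fraction_of_train: float = 0.2
    n_trees: int = 30
    max_depth: int = 8
    min_leaf: int = 5
    hypertension_threshold_mmhg: float = 15.0
    loa_z: float = 1.96
    min_pulses_per_window: int = 20
    rng_seed: int = 0
    hr_bounds_bpm: tuple[float, float] = (40.0, 180.0)
    saturation_margin: float = 0.005
    artifact_z: float = 5.0

    def __post_init__(self) -> None:
        self.ac_band_hz = tuple(float(v) for v in self.ac_band_hz)  # type: ignore[assignment]
        self.hr_bounds_bpm = tuple(float(v) for v in self.hr_bounds_bpm)  # type: ignore[assignment]
        self.validate()

    def validate(self) -> None:
        lo, hi = self.ac_band_hz
        if not 0 < lo < hi:
            raise ValueError(f"invalid AC band {self.ac_band_hz}")
        if self.dc_cut_hz <= 0:
            raise ValueError("dc_cut_hz must be positive")
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")
        if not 0 <= self.val_fraction_of_train < 1:
            raise ValueError("val_fraction_of_train must be in [0, 1)")
        if not self.icp_min_mmhg < self.icp_max_mmhg:
            raise ValueError("icp_min_mmhg must be below icp_max_mmhg")
        span = self.icp_max_mmhg - self.icp_min_mmhg
        n_bins = span / self.bin_width_mmhg
        if abs(n_bins - round(n_bins)) > 1e-9:
            raise ValueError("bin_width_mmhg must divide the ICP range")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if self.min_leaf < 1:
            raise ValueError("min_leaf must be >= 1")
        if self.min_pulses_per_window < 1:
            raise ValueError("min_pulses_per_window must be >= 1")
        hr_lo, hr_hi = self.hr_bounds_bpm
        if not 0 < hr_lo < hr_hi:
            raise ValueError(f"invalid hr_bounds_bpm {self.hr_bounds_bpm}")
        if self.window_s <= 0 or self.norm_factor <= 0 or self.filter_order < 1:
            raise ValueError("window_s, norm_factor and filter_order must be positive")

    @property
    def n_bins(self) -> int:
        return int(round((self.icp_max_mmhg - self.icp_min_mmhg) / self.bin_width_mmhg))

    def replace(self, **overrides: Any) -> "AnalysisConfig":
        return dataclasses.replace(self, **overrides)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["ac_band_hz"] = list(self.ac_band_hz)
        d["hr_bounds_bpm"] = list(self.hr_bounds_bpm)
        return d


def load_config(path: str | Path | None = None, **overrides: Any) -> AnalysisConfig:
    """Build an :class:`AnalysisConfig` from defaults, an optional YAML file
    and keyword overrides (highest precedence)."""
    values: dict[str, Any] = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        known = {f.name for f in dataclasses.fields(AnalysisConfig)}
        unknown = set(loaded) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        values.update(loaded)
    values.update(overrides)
    return AnalysisConfig(**values)
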