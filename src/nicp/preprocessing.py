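"""Artifact removal and AC/DC decomposition of the cerebral PPG.

Movement artifacts and photodetector saturation are detected on the raw PPG
and removed *synchronously* from PPG and invasive ICP, so the two never drift
out of alignment. Each surviving contiguous span is then decomposed with
zero-phase Butterworth filters into a cardiac AC component (bandpass) and a
baseline DC component (lowpass), and normalized as ``norm_factor * AC / DC``
to cancel optical gain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.ndimage import binary_dilation, median_filter

from .config import AnalysisConfig
from .core import SampledSignal, SessionRecording

__all__ = [
    "ArtifactMask",
    "RawSpan",
    "CleanSegment",
    "DenoisingReport",
    "detect_artifacts",
    "remove_synchronous",
    "extract_ac",
    "extract_dc",
    "normalize",
    "preprocess_session",
    "band_snr_db",
]

logger = logging.getLogger(__name__)

# Fixed detector constants (seconds); the tunable thresholds live in config.
SATURATION_RUN_S = 0.05  # minimum time spanned by a near-rail run
ARTIFACT_WINDOW_S = 1.0  # sliding-window length for the movement detector
ARTIFACT_DILATE_S = 0.5  # guard band added around every flagged region
MIN_SPAN_S = 10.0  # spans shorter than this cannot be filtered reliably

REASON_NONE = 0
REASON_SATURATION = 1
REASON_MOVEMENT = 2
_REASON_NAMES = {REASON_NONE: "none", REASON_SATURATION: "saturation", REASON_MOVEMENT: "movement"}


@dataclass
class ArtifactMask:
    """Per-sample artifact verdicts: ``bad`` plus a reason code."""

    bad: np.ndarray  # bool, same length as the signal
    reasons: np.ndarray  # int8 codes, see REASON_*

    def __post_init__(self) -> None:
        self.bad = np.asarray(self.bad, dtype=bool)
        self.reasons = np.asarray(self.reasons, dtype=np.int8)
        if self.bad.shape != self.reasons.shape:
            raise ValueError("mask arrays must share a shape")

    def reason_names(self) -> np.ndarray:
        return np.vectorize(_REASON_NAMES.get)(self.reasons)


@dataclass
class RawSpan:
    """A maximal contiguous artifact-free span, still unfiltered."""

    start_index: int
    ppg: SampledSignal
    icp: SampledSignal


@dataclass
class CleanSegment:
    """A filtered, normalized span ready for pulse analysis."""

    start_index: int
    ppg_norm: SampledSignal
    ppg_dc: SampledSignal
    icp: SampledSignal

    def __post_init__(self) -> None:
        if not (len(self.ppg_norm) == len(self.ppg_dc) == len(self.icp)):
            raise ValueError("segment signals must share a length")

    @property
    def start_time_s(self) -> float:
        return self.start_index / self.ppg_norm.rate


@dataclass
class DenoisingReport:
    """Accounting of what the denoiser removed and what it achieved."""

    total_s: float
    retained_s: float
    retained_fraction: float
    snr_before_db: float
    snr_after_db: float

    def to_dict(self) -> dict[str, float]:
        return {
            "total_h": self.total_s / 3600.0,
            "retained_h": self.retained_s / 3600.0,
            "retained_fraction": self.retained_fraction,
            "snr_before_db": self.snr_before_db,
            "snr_after_db": self.snr_after_db,
        }


def _flag_runs(
    flag: np.ndarray, min_len: int, x: np.ndarray | None = None, max_ptp: float = np.inf
) -> np.ndarray:
    """Keep only True-runs of at least ``min_len`` samples (and, when ``x``
    is given, with peak-to-peak excursion at most ``max_ptp`` — a plateau)."""
    out = np.zeros_like(flag)
    if not flag.any():
        return out
    edges = np.flatnonzero(np.diff(np.concatenate(([False], flag, [False])).astype(np.int8)))
    for start, stop in zip(edges[::2], edges[1::2]):
        if stop - start < min_len:
            continue
        if x is not None and np.ptp(x[start:stop]) > max_ptp:
            continue
        out[start:stop] = True
    return out


def detect_artifacts(sig: SampledSignal, cfg: AnalysisConfig) -> ArtifactMask:
    """Flag photodetector saturation and movement artifacts.

    Saturation: samples within ``saturation_margin`` of the session's rails
    (running min/max), in runs spanning at least ``SATURATION_RUN_S``.
    Movement: 1-s sliding windows whose peak-to-peak amplitude deviates from
    the session median by more than ``artifact_z`` robust (MAD) z-scores.
    Every flagged region is dilated by 0.5 s on each side.
    """
    x = sig.values
    rate = sig.rate
    if x.size < rate:
        raise ValueError("signal shorter than one analysis window (1 s)")

    lo, hi = float(np.min(x)), float(np.max(x))
    span = hi - lo
    margin = cfg.saturation_margin * span if span > 0 else 0.0
    near_rail = (x >= hi - margin) | (x <= lo + margin)
    # a run of n samples spans (n-1)/rate seconds; a saturated run is pinned
    # at the rail, so it must also be flat (quiescent baseline passing near
    # the observed minimum is not saturation)
    min_run = int(np.floor(SATURATION_RUN_S * rate)) + 1
    sat = (
        _flag_runs(near_rail, min_run, x=x, max_ptp=0.25 * margin)
        if span > 0
        else np.ones_like(near_rail)
    )

    w = max(2, int(round(ARTIFACT_WINDOW_S * rate)))
    hop = max(1, w // 2)
    starts = np.arange(0, x.size - w + 1, hop)
    movement = np.zeros(x.size, dtype=bool)
    if starts.size >= 3:
        windows = np.lib.stride_tricks.sliding_window_view(x, w)[starts]
        p2p = windows.max(axis=1) - windows.min(axis=1)
        # deviation from a *local* (2-min rolling) median so slow physiologic
        # amplitude changes are not mistaken for movement; bursts of seconds
        # still stick out sharply
        local_w = min(p2p.size, 241) | 1
        local_med = median_filter(p2p, size=local_w, mode="nearest")
        resid = p2p - local_med
        med = np.median(p2p)
        mad = np.median(np.abs(resid))
        # MAD floor at 5% of the median p2p: a clean quasi-periodic signal has
        # tiny MAD and would otherwise flag benign respiratory variation
        scale = max(mad, 0.05 * abs(med), 1e-12)
        bad_win = np.abs(resid) / scale > cfg.artifact_z
        for s in starts[bad_win]:
            movement[s : s + w] = True

    dilate = int(round(ARTIFACT_DILATE_S * rate))
    structure = np.ones(2 * dilate + 1, dtype=bool)
    if sat.any():
        sat = binary_dilation(sat, structure=structure)
    if movement.any():
        movement = binary_dilation(movement, structure=structure)

    reasons = np.zeros(x.size, dtype=np.int8)
    reasons[movement] = REASON_MOVEMENT
    reasons[sat] = REASON_SATURATION  # saturation wins where both fire
    return ArtifactMask(bad=sat | movement, reasons=reasons)


def remove_synchronous(
    rec: SessionRecording, mask: ArtifactMask, cfg: AnalysisConfig
) -> list[RawSpan]:
    """Cut PPG and ICP identically around masked samples.

    Returns the maximal contiguous unmasked spans of at least ``MIN_SPAN_S``;
    gaps are never bridged.
    """
    if mask.bad.size != len(rec.ppg_distal):
        raise ValueError("mask length does not match the distal PPG")
    good = ~mask.bad
    min_len = int(round(MIN_SPAN_S * rec.rate))
    spans: list[RawSpan] = []
    edges = np.flatnonzero(np.diff(np.concatenate(([False], good, [False])).astype(np.int8)))
    for start, stop in zip(edges[::2], edges[1::2]):
        if stop - start < min_len:
            continue
        spans.append(
            RawSpan(
                start_index=int(start),
                ppg=rec.ppg_distal.slice(start, stop),
                icp=rec.icp.slice(start, stop),
            )
        )
    return spans


def _butter_sos(cfg: AnalysisConfig, rate: float, kind: str) -> np.ndarray:
    if kind == "bandpass":
        if rate < 2 * cfg.ac_band_hz[1]:
            raise ValueError(
                f"sampling rate {rate} Hz below twice the upper AC cutoff {cfg.ac_band_hz[1]} Hz"
            )
        return sps.butter(cfg.filter_order, cfg.ac_band_hz, btype="bandpass", fs=rate, output="sos")
    return sps.butter(cfg.filter_order, cfg.dc_cut_hz, btype="lowpass", fs=rate, output="sos")


def extract_ac(sig: SampledSignal, cfg: AnalysisConfig) -> SampledSignal:
    """Cardiac component: zero-phase 2nd-order Butterworth bandpass (0.8-10 Hz)."""
    sos = _butter_sos(cfg, sig.rate, "bandpass")
    return SampledSignal(sps.sosfiltfilt(sos, sig.values), sig.rate, sig.t0)


def extract_dc(sig: SampledSignal, cfg: AnalysisConfig) -> SampledSignal:
    """Baseline component: zero-phase 2nd-order Butterworth lowpass (0.1 Hz)."""
    sos = _butter_sos(cfg, sig.rate, "lowpass")
    return SampledSignal(sps.sosfiltfilt(sos, sig.values), sig.rate, sig.t0)


class DCFloorError(ValueError):
    """DC baseline too close to zero for a meaningful AC/DC ratio."""


def normalize(ac: SampledSignal, dc: SampledSignal, cfg: AnalysisConfig) -> SampledSignal:
    """Perfusion-style normalization ``norm_factor * ac / dc``.

    The DC trace must stay above ``1e-3 * median(|dc|)`` everywhere; spans
    violating the floor are rejected (treated as artifact) because the ratio
    would blow up.
    """
    if len(ac) != len(dc):
        raise ValueError("AC and DC must have equal lengths")
    dcv = dc.values
    floor = 1e-3 * np.median(np.abs(dcv))
    if np.any(np.abs(dcv) < floor):
        raise DCFloorError("DC component below floor; span rejected")
    return SampledSignal(cfg.norm_factor * ac.values / dcv, ac.rate, ac.t0)


def band_snr_db(x: np.ndarray, rate: float, band: tuple[float, float] = (0.8, 10.0)) -> float:
    """SNR as 10*log10(power in ``band`` / power outside), via Welch PSD."""
    if x.size < 4:
        return float("nan")
    nperseg = min(x.size, int(round(30 * rate)))
    f, pxx = sps.welch(x - np.mean(x), fs=rate, nperseg=nperseg)
    inside = (f >= band[0]) & (f <= band[1])
    p_in = np.trapezoid(pxx[inside], f[inside])
    p_out = np.trapezoid(pxx[~inside], f[~inside])
    if p_out <= 0:
        return float("inf")
    return float(10.0 * np.log10(p_in / p_out))


def preprocess_session(
    rec: SessionRecording, cfg: AnalysisConfig
) -> tuple[list[CleanSegment], DenoisingReport]:
    """Full preprocessing of one session.

    Detect artifacts on the distal PPG, cut them synchronously from PPG and
    ICP, then filter and normalize each surviving span. Returns the clean
    segments plus a denoising report (retained fraction and in-band SNR
    before/after).
    """
    mask = detect_artifacts(rec.ppg_distal, cfg)
    spans = remove_synchronous(rec, mask, cfg)
    segments: list[CleanSegment] = []
    retained = 0
    for span in spans:
        ac = extract_ac(span.ppg, cfg)
        dc = extract_dc(span.ppg, cfg)
        try:
            norm = normalize(ac, dc, cfg)
        except DCFloorError:
            logger.info("span at %d rejected: DC floor", span.start_index)
            continue
        segments.append(
            CleanSegment(start_index=span.start_index, ppg_norm=norm, ppg_dc=dc, icp=span.icp)
        )
        retained += len(span.ppg)

    total_s = rec.ppg_distal.duration_s
    retained_s = retained / rec.rate
    raw = rec.ppg_distal.values
    kept = (
        np.concatenate([rec.ppg_distal.values[s.start_index : s.start_index + len(s.icp)] for s in segments])
        if segments
        else np.empty(0)
    )
    report = DenoisingReport(
        total_s=total_s,
        retained_s=retained_s,
        retained_fraction=retained_s / total_s if total_s else 0.0,
        snr_before_db=band_snr_db(raw, rec.rate, cfg.ac_band_hz),
        snr_after_db=band_snr_db(kept, rec.rate, cfg.ac_band_hz),
    )
    logger.info(
        "session %s: retained %.1f of %.1f s (%.1f%%)",
        rec.patient_id,
        retained_s,
        total_s,
        100 * report.retained_fraction,
    )
    return segments, report
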