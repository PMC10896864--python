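"""Cardiac pulse segmentation, fiducial points and morphology features.

The normalized AC PPG is cut into foot-to-foot pulses at the minima between
systolic peaks. Per pulse we locate the systolic peak and (when present) the
dicrotic notch, and compute 11 time-domain morphology features. Feature
definitions follow standard PPG-morphology conventions: width at half
amplitude, secant slopes (amplitude over time), trapezoidal areas split at
the dicrotic notch (falling back to the peak when no notch exists, so
systolic + diastolic area always equals the total area), and the signed
max/min ratio of the Savitzky-Golay second derivative (SDPPG).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from ._savgol import savgol
from .config import AnalysisConfig
from .core import SampledSignal

__all__ = [
    "PulseSegment",
    "Fiducials",
    "segment_pulses",
    "locate_fiducials",
    "second_derivative",
    "compute_features",
    "DegeneratePulseError",
    "pulse_records",
]

SG_WINDOW_S = 0.11  # Savitzky-Golay window (scaled with rate, odd samples)
SG_ORDER = 3
MIN_PULSE_SAMPLES = 15
NOTCH_SMOOTH_S = 0.05


class DegeneratePulseError(ValueError):
    """Pulse whose features are undefined (e.g. zero diastolic area)."""


@dataclass
class PulseSegment:
    """One cardiac pulse of normalized AC PPG, foot to next foot."""

    samples: np.ndarray
    rate: float
    foot_value: float
    start_index: int = 0  # index of the foot within the parent span

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return (self.samples.size - 1) / self.rate


@dataclass
class Fiducials:
    """Landmark indices within a pulse; the notch may be absent."""

    foot_idx: int
    peak_idx: int
    end_idx: int
    notch_idx: int | None = None

    def __post_init__(self) -> None:
        ok = self.foot_idx < self.peak_idx <= (
            self.notch_idx if self.notch_idx is not None else self.peak_idx
        ) < self.end_idx
        if not ok:
            raise ValueError("fiducials must satisfy foot < peak <= notch < end")


def _median_p2p(x: np.ndarray, rate: float) -> float:
    """Median 1-s peak-to-peak amplitude of a span."""
    w = max(2, int(round(rate)))
    if x.size < w:
        return float(np.ptp(x))
    starts = np.arange(0, x.size - w + 1, max(1, w // 2))
    windows = np.lib.stride_tricks.sliding_window_view(x, w)[starts]
    return float(np.median(windows.max(axis=1) - windows.min(axis=1)))


def segment_pulses(ppg_norm: SampledSignal, cfg: AnalysisConfig) -> list[PulseSegment]:
    """Cut a clean span into foot-to-foot cardiac pulses.

    Systolic peaks are local maxima separated by at least one minimal
    cardiac period (60/hr_max) with prominence >= 25% of the span's median
    peak-to-peak amplitude; feet are the minima between consecutive peaks.
    Pulses with implausible duration (outside the heart-rate bounds) or
    outlier amplitude (> 3 MAD from the span median) are dropped.
    """
    x = ppg_norm.values
    rate = ppg_norm.rate
    hr_lo, hr_hi = cfg.hr_bounds_bpm
    med_p2p = _median_p2p(x, rate)
    if med_p2p <= 0:
        return []
    peaks, _ = sps.find_peaks(
        x,
        distance=max(1, int(round(rate * 60.0 / hr_hi))),
        prominence=0.25 * med_p2p,
    )
    if peaks.size < 3:
        return []
    inner = [p0 + int(np.argmin(x[p0 : p1 + 1])) for p0, p1 in zip(peaks[:-1], peaks[1:])]
    # boundary feet so edge beats form pulses too; plausibility filters below
    # drop them when the span starts or ends mid-pulse
    first = int(np.argmin(x[: peaks[0] + 1]))
    last = peaks[-1] + int(np.argmin(x[peaks[-1] :]))
    feet = np.unique(np.array([first] + inner + [last], dtype=np.intp))
    candidates: list[PulseSegment] = []
    for f0, f1 in zip(feet[:-1], feet[1:]):
        dur = (f1 - f0) / rate
        if not (60.0 / hr_hi <= dur <= 60.0 / hr_lo):
            continue
        seg = x[f0 : f1 + 1]
        if seg.size < MIN_PULSE_SAMPLES:
            continue
        candidates.append(
            PulseSegment(samples=seg, rate=rate, foot_value=float(x[f0]), start_index=int(f0))
        )
    if not candidates:
        return []
    amps = np.array([np.max(p.samples) - p.foot_value for p in candidates])
    med = np.median(amps)
    mad = np.median(np.abs(amps - med))
    # floor the MAD so near-identical clean pulses are not culled
    scale = max(mad, 0.05 * abs(med), 1e-12)
    keep = np.abs(amps - med) / scale <= 3.0
    return [p for p, k in zip(candidates, keep) if k]


def locate_fiducials(p: PulseSegment, cfg: AnalysisConfig) -> Fiducials:
    """Foot (index 0), systolic peak (global maximum) and dicrotic notch.

    The notch is the first local minimum of the lightly smoothed pulse after
    the peak; when none exists the notch is absent and the systolic/diastolic
    boundary falls back to the peak.
    """
    x = p.samples
    end = x.size - 1
    peak = int(np.argmax(x))
    peak = max(1, min(peak, end - 1))
    w = int(round(NOTCH_SMOOTH_S * p.rate))
    w = max(3, w + (w + 1) % 2)  # odd, >= 3
    smooth = savgol(x, w, 2) if x.size > w else x
    notch: int | None = None
    for i in range(peak + 1, end):
        if smooth[i] <= smooth[i - 1] and smooth[i] < smooth[i + 1]:
            notch = i
            break
    return Fiducials(foot_idx=0, peak_idx=peak, end_idx=end, notch_idx=notch)


def _sg_window(rate: float, n: int) -> int:
    w = int(round(SG_WINDOW_S * rate))
    w = max(SG_ORDER + 2, w + (w + 1) % 2)  # odd and large enough for order 3
    if w > n:
        w = n if n % 2 == 1 else n - 1
    return w


def second_derivative(p: PulseSegment, cfg: AnalysisConfig) -> np.ndarray:
    """SDPPG: Savitzky-Golay smoothing-differentiation applied twice.

    Local cubic fits over a 110 ms window (scaled with the sampling rate)
    suppress the noise amplification of double differencing; output length
    equals the pulse length, edges handled by the polynomial fit.
    """
    x = p.samples
    if x.size < MIN_PULSE_SAMPLES:
        raise ValueError(f"pulse too short for SDPPG ({x.size} samples)")
    w = _sg_window(p.rate, x.size)
    d1 = savgol(x, w, SG_ORDER, deriv=1, delta=1.0 / p.rate)
    d2 = savgol(d1, w, SG_ORDER, deriv=1, delta=1.0 / p.rate)
    return d2


def _half_width(y: np.ndarray, rate: float, amp: float) -> float:
    """Width at half amplitude: first up-crossing to last down-crossing,
    linearly interpolated between samples."""
    half = amp / 2.0
    above = y >= half
    idx = np.flatnonzero(above)
    if idx.size == 0:
        return 0.0
    i_up = idx[0]
    if i_up == 0:
        t_up = 0.0
    else:
        y0, y1 = y[i_up - 1], y[i_up]
        t_up = (i_up - 1 + (half - y0) / (y1 - y0)) / rate
    i_dn = idx[-1]
    if i_dn == y.size - 1:
        t_dn = (y.size - 1) / rate
    else:
        y0, y1 = y[i_dn], y[i_dn + 1]
        t_dn = (i_dn + (y0 - half) / (y0 - y1)) / rate
    return t_dn - t_up


def compute_features(p: PulseSegment, f: Fiducials, cfg: AnalysisConfig) -> dict[str, float]:
    """The 11 time-domain morphology features of one pulse.

    All amplitudes are measured after subtracting the foot value. Areas are
    trapezoidal integrals in (normalized-PPG) x seconds; the systolic/
    diastolic boundary is the dicrotic notch, or the peak when absent.
    """
    y = p.samples - p.foot_value
    dt = 1.0 / p.rate
    amp = float(y[f.peak_idx])
    if amp <= 0:
        raise DegeneratePulseError("non-positive pulse amplitude")
    rise = (f.peak_idx - f.foot_idx) * dt
    decay = (f.end_idx - f.peak_idx) * dt
    if rise <= 0 or decay <= 0:
        raise DegeneratePulseError("degenerate rise or decay time")
    boundary = f.notch_idx if f.notch_idx is not None else f.peak_idx
    auc = float(np.trapezoid(y, dx=dt))
    sys_area = float(np.trapezoid(y[: boundary + 1], dx=dt))
    dia_area = auc - sys_area
    if dia_area == 0:
        raise DegeneratePulseError("zero diastolic area")
    d2 = second_derivative(p, cfg)
    edge = _sg_window(p.rate, len(p)) // 2
    interior = d2[edge : len(p) - edge] if len(p) > 2 * edge + 2 else d2
    d2_max, d2_min = float(np.max(interior)), float(np.min(interior))
    if d2_min == 0:
        raise DegeneratePulseError("flat second derivative")
    return {
        "amplitude": amp,
        "pulse_width_s": _half_width(y, p.rate, amp),
        "rise_time_s": rise,
        "decay_time_s": decay,
        "upslope_per_s": amp / rise,
        "downslope_per_s": -amp / decay,
        "auc": auc,
        "sys_area": sys_area,
        "dia_area": dia_area,
        "sys_dia_ratio": sys_area / dia_area,
        "sdppg_ratio": d2_max / d2_min,
    }


def pulse_records(
    ppg_norm: SampledSignal, cfg: AnalysisConfig, span_start_index: int = 0
) -> list[tuple[float, dict[str, float]]]:
    """Segment a span and compute features for every accepted pulse.

    Returns ``(absolute_foot_time_s, features)`` pairs; pulses with
    degenerate morphology are silently dropped.
    """
    out: list[tuple[float, dict[str, float]]] = []
    for pulse in segment_pulses(ppg_norm, cfg):
        try:
            fid = locate_fiducials(pulse, cfg)
            feats = compute_features(pulse, fid, cfg)
        except (DegeneratePulseError, ValueError):
            continue
        t_foot = (span_start_index + pulse.start_index) / ppg_norm.rate
        out.append((t_foot, feats))
    return out
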