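"""Synthetic PPG/ICP session generator with known ground truth.

The generator embodies the working hypothesis of PPG-based ICP monitoring:
intracranial pressure modulates the morphology of the cerebral pulse. Each
cardiac pulse is a two-Gaussian waveform (systolic wave plus delayed dicrotic
wave) whose per-beat parameters follow the local ICP through a monotone
morphology map — amplitude falls, rise time lengthens and the dicrotic wave
grows as ICP rises. The raw optical signal adds a large slowly drifting DC
baseline, respiration-band modulation, white noise, and injected artifacts
(saturation plateaus at the rail, movement-noise bursts) at recorded
intervals, so every pipeline stage can be checked against ground truth.

The two-Gaussian pulse model is chosen for its closed forms: fiducial
locations, areas and derivatives are analytic, which makes it usable as an
oracle for the feature extractor. It is a test harness, not a physiological
claim; the true quantitative ICP-to-morphology mapping in patients is
unknown.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import SampledSignal, SessionRecording

__all__ = ["SimParams", "GroundTruth", "simulate_icp", "simulate_session", "simulate_patient"]

ICP_REF_MMHG = 12.0  # map reference pressure: morphology at this ICP is nominal


@dataclass
class SimParams:
    """Synthetic study conditions.

    Morphology-map gains are per mmHg of ICP above/below ``ICP_REF_MMHG``;
    setting all three to zero yields a PPG carrying no ICP information (the
    negative control).
    """

    duration_s: float = 14400.0  # 4 h of monitoring
    rate_hz: float = 100.0
    icp_base_mmhg: float = 12.0
    icp_sd_mmhg: float = 2.5
    icp_range: tuple[float, float] = (5.0, 40.0)
    n_hypertension_events: int = 2
    event_height_mmhg: float = 14.0
    hr_mean_bpm: float = 70.0
    hr_sd_bpm: float = 3.0
    amplitude_gain_per_mmhg: float = -0.025
    rise_gain_per_mmhg: float = 0.010
    notch_gain_per_mmhg: float = 0.012
    respiration_hz: float = 0.25
    respiration_depth: float = 0.5
    drift_hz: float = 0.01
    drift_depth: float = 2.0
    dc_level: float = 100.0
    pulse_amplitude: float = 1.0
    noise_sd: float = 0.03
    artifact_fraction: float = 0.05
    saturation_rails: tuple[float, float] = (0.0, 150.0)
    seed: int = 0

    # nominal pulse shape (seconds / dimensionless)
    sys_center_s: float = 0.15
    sys_width_s: float = 0.045
    dicrotic_delay_s: float = 0.22
    dicrotic_width_s: float = 0.09
    dicrotic_ratio: float = 0.35

    def __post_init__(self) -> None:
        if self.rate_hz <= 0 or self.duration_s <= 0 or self.hr_mean_bpm <= 0:
            raise ValueError("rates and durations must be positive")
        if not 0 <= self.artifact_fraction <= 0.5:
            raise ValueError("artifact_fraction must be in [0, 0.5]")
        lo, hi = self.icp_range
        if not (5.0 <= lo < hi <= 40.0):
            raise ValueError("icp_range must lie within [5, 40] mmHg")


@dataclass
class GroundTruth:
    """What the generator actually did, for oracle-style assertions."""

    beat_times_s: np.ndarray
    beat_amplitude: np.ndarray
    beat_rise_s: np.ndarray
    beat_dicrotic_ratio: np.ndarray
    beat_icp_mmhg: np.ndarray
    artifact_intervals: list[tuple[float, float, str]] = field(default_factory=list)
    icp: SampledSignal | None = None

    @property
    def artifact_seconds(self) -> float:
        return sum(e - s for s, e, _ in self.artifact_intervals)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def simulate_icp(
    p: SimParams, rng: np.random.Generator | None = None
) -> tuple[SampledSignal, list[tuple[float, float, float]]]:
    """Slowly varying ICP: mean-reverting walk plus smooth plateau events.

    The walk runs on a 1-s grid (ICP dynamics are slow relative to the
    cardiac cycle) and is interpolated to the sampling rate; the default
    parameters keep most of the trace in the normal range, reproducing the
    skew toward low pressures seen in sedated patients. Returns the trace
    and the injected (start_s, end_s, height_mmhg) events.
    """
    rng = np.random.default_rng(p.seed) if rng is None else rng
    n_coarse = int(np.ceil(p.duration_s)) + 1
    theta = 0.005
    sigma = p.icp_sd_mmhg * np.sqrt(2.0 * theta)
    steps = sigma * rng.standard_normal(n_coarse)
    x = np.empty(n_coarse)
    x[0] = p.icp_base_mmhg
    for k in range(1, n_coarse):
        x[k] = x[k - 1] + theta * (p.icp_base_mmhg - x[k - 1]) + steps[k]
    t_coarse = np.arange(n_coarse, dtype=np.float64)

    events: list[tuple[float, float, float]] = []
    for _ in range(p.n_hypertension_events):
        height = float(rng.uniform(0.6, 1.0) * p.event_height_mmhg)
        start = float(rng.uniform(0.05, 0.75) * p.duration_s)
        hold = float(rng.uniform(180.0, 600.0))
        end = min(start + hold, 0.98 * p.duration_s)
        ramp = 60.0
        x += height * (_sigmoid((t_coarse - start) / ramp) - _sigmoid((t_coarse - end) / ramp))
        events.append((start, end, height))

    n = int(round(p.duration_s * p.rate_hz))
    t = np.arange(n) / p.rate_hz
    icp = np.interp(t, t_coarse, x)
    np.clip(icp, p.icp_range[0], p.icp_range[1], out=icp)
    return SampledSignal(icp, p.rate_hz), events


def _two_gaussian(
    tau: np.ndarray, amp: float, mu1: float, s1: float, mu2: float, s2: float, ratio: float
) -> np.ndarray:
    return amp * (
        np.exp(-0.5 * ((tau - mu1) / s1) ** 2) + ratio * np.exp(-0.5 * ((tau - mu2) / s2) ** 2)
    )


def simulate_session(
    icp: SampledSignal,
    p: SimParams,
    rng: np.random.Generator | None = None,
    patient_id: str = "sim",
) -> tuple[SessionRecording, GroundTruth]:
    """Synthesize the optical channels for a given ICP trace.

    The distal (cerebral) channel carries the ICP-dependent morphology; the
    proximal (extracerebral) channel is an attenuated, ICP-independent pulse
    train on the same beats.
    """
    rng = np.random.default_rng(p.seed + 1) if rng is None else rng
    rate = p.rate_hz
    n = len(icp)
    dur = n / rate

    # beat onsets: Gaussian inter-beat process
    ibi_mean = 60.0 / p.hr_mean_bpm
    ibi_sd = ibi_mean * p.hr_sd_bpm / p.hr_mean_bpm
    n_beats_max = int(dur / ibi_mean * 1.5) + 10
    ibis = np.clip(rng.normal(ibi_mean, ibi_sd, n_beats_max), 0.4 * ibi_mean, 2.0 * ibi_mean)
    beat_times = np.concatenate(([0.0], np.cumsum(ibis)))
    beat_times = beat_times[beat_times < dur - ibi_mean]

    beat_idx = np.minimum((beat_times * rate).astype(np.intp), n - 1)
    beat_icp = icp.values[beat_idx]
    d = beat_icp - ICP_REF_MMHG
    amp = p.pulse_amplitude * np.exp(p.amplitude_gain_per_mmhg * d)
    mu1 = np.clip(p.sys_center_s * (1.0 + p.rise_gain_per_mmhg * d), 0.08, 0.35)
    ratio = np.clip(p.dicrotic_ratio * (1.0 + p.notch_gain_per_mmhg * d), 0.05, 0.9)

    ac = np.zeros(n)
    ac_prox = np.zeros(n)
    starts = np.minimum((beat_times * rate).astype(np.intp), n - 1)
    stops = np.append(starts[1:], n)
    for i, (i0, i1) in enumerate(zip(starts, stops)):
        tau = (np.arange(i0, i1) - i0) / rate
        ac[i0:i1] += _two_gaussian(
            tau, amp[i], mu1[i], p.sys_width_s, mu1[i] + p.dicrotic_delay_s, p.dicrotic_width_s, ratio[i]
        )
        ac_prox[i0:i1] += _two_gaussian(
            tau,
            p.pulse_amplitude,
            p.sys_center_s,
            p.sys_width_s,
            p.sys_center_s + p.dicrotic_delay_s,
            p.dicrotic_width_s,
            p.dicrotic_ratio,
        )

    t = np.arange(n) / rate
    ph1, ph2 = rng.uniform(0, 2 * np.pi, 2)
    dc = (
        p.dc_level
        + p.drift_depth * np.sin(2 * np.pi * p.drift_hz * t + ph1)
        + p.respiration_depth * np.sin(2 * np.pi * p.respiration_hz * t + ph2)
    )
    raw = dc + ac + rng.normal(0.0, p.noise_sd, n) if p.noise_sd > 0 else dc + ac
    raw_prox = 0.5 * (dc + ac_prox)
    if p.noise_sd > 0:
        raw_prox = raw_prox + rng.normal(0.0, 0.5 * p.noise_sd, n)

    # injected artifacts at recorded intervals
    intervals: list[tuple[float, float, str]] = []
    if p.artifact_fraction > 0:
        budget_mv = 0.8 * p.artifact_fraction * dur
        budget_sat = 0.2 * p.artifact_fraction * dur
        used = 0.0
        while used < budget_mv:
            length = float(rng.uniform(2.0, 8.0))
            start = float(rng.uniform(0.0, dur - length))
            i0, i1 = int(start * rate), int((start + length) * rate)
            raw[i0:i1] += rng.normal(0.0, 10.0 * p.pulse_amplitude, i1 - i0)
            intervals.append((start, start + length, "movement"))
            used += length
        used = 0.0
        while used < budget_sat:
            length = float(rng.uniform(0.5, 3.0))
            start = float(rng.uniform(0.0, dur - length))
            i0, i1 = int(start * rate), int((start + length) * rate)
            raw[i0:i1] = p.saturation_rails[1]
            intervals.append((start, start + length, "saturation"))
            used += length
        intervals.sort()

    rec = SessionRecording(
        patient_id=patient_id,
        ppg_distal=SampledSignal(raw, rate),
        icp=icp,
        ppg_proximal=SampledSignal(raw_prox, rate),
    )
    truth = GroundTruth(
        beat_times_s=beat_times,
        beat_amplitude=amp,
        beat_rise_s=mu1,
        beat_dicrotic_ratio=ratio,
        beat_icp_mmhg=beat_icp,
        artifact_intervals=_merge_intervals(intervals),
        icp=icp,
    )
    return rec, truth


def _merge_intervals(
    intervals: list[tuple[float, float, str]]
) -> list[tuple[float, float, str]]:
    merged: list[tuple[float, float, str]] = []
    for s, e, kind in sorted(intervals):
        if merged and s <= merged[-1][1] and kind == merged[-1][2]:
            ps, pe, pk = merged[-1]
            merged[-1] = (ps, max(pe, e), pk)
        else:
            merged.append((s, e, kind))
    return merged


def simulate_patient(p: SimParams, patient_id: str = "sim") -> tuple[SessionRecording, GroundTruth]:
    """One synthetic patient: ICP trajectory plus both optical channels.

    All randomness flows from ``p.seed``; identical params produce
    bit-identical sessions.
    """
    rng = np.random.default_rng(p.seed)
    icp, _events = simulate_icp(p, rng)
    return simulate_session(icp, p, rng, patient_id=patient_id)
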