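"""Pulse segmentation, fiducials and the 11 morphology features."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize_scalar
from scipy.special import erf

from conftest import pulse_train, two_gaussian_pulse
from nicp.config import AnalysisConfig
from nicp.core import FEATURE_NAMES, SampledSignal
from nicp.pulses import (
    DegeneratePulseError,
    Fiducials,
    PulseSegment,
    compute_features,
    locate_fiducials,
    pulse_records,
    second_derivative,
    segment_pulses,
)


def _triangle(rise_s=0.2, decay_s=0.4, amp=1.0, rate=100.0):
    up = np.linspace(0, amp, int(rise_s * rate) + 1)
    down = np.linspace(amp, 0, int(decay_s * rate) + 1)[1:]
    return PulseSegment(np.concatenate([up, down]), rate, 0.0)


class TestSegmentPulses:
    def test_60bpm_train_yields_one_pulse_per_beat(self, cfg):
        beats = np.arange(0.0, 59.0, 1.0)
        pulses = segment_pulses(pulse_train(beats, 60.0), cfg)
        assert abs(len(pulses) - len(beats)) <= 1

    def test_constant_signal_empty(self, cfg):
        assert segment_pulses(SampledSignal(np.full(2000, 3.0), 100.0), cfg) == []

    def test_outlier_pulses_dropped_and_feet_accurate(self, cfg):
        """75 bpm train with every 10th beat amplitude x5: outliers culled,
        detected feet within 50 ms of the generator's beat onsets."""
        rng = np.random.default_rng(5)
        ibi, dur = 0.8, 120.0
        beats = np.arange(0.0, dur - 1.0, ibi) + rng.normal(0, 0.01, 149)
        amps = np.where(np.arange(149) % 10 == 9, 5.0, 1.0)
        pulses = segment_pulses(pulse_train(beats, dur, amplitudes=amps), cfg)
        n_regular = int((amps == 1.0).sum())
        assert abs(len(pulses) - n_regular) <= 1
        feet_t = np.array([p.start_index / 100.0 for p in pulses])
        dist = np.min(np.abs(feet_t[:, None] - beats[None, :]), axis=1)
        assert np.mean(dist <= 0.05) >= 0.95

    def test_implausible_durations_rejected(self, cfg):
        beats = np.arange(0.0, 58.0, 2.0)  # 30 bpm, below the 40 bpm floor
        assert segment_pulses(pulse_train(beats, 60.0), cfg) == []


class TestFiducials:
    def test_two_gaussian_notch_matches_analytic_minimum(self, cfg):
        x, prm = two_gaussian_pulse()
        p = PulseSegment(x, 100.0, float(x[0]))
        fid = locate_fiducials(p, cfg)
        assert fid.notch_idx is not None
        g = lambda t: prm["amp"] * (
            np.exp(-0.5 * ((t - prm["mu1"]) / prm["s1"]) ** 2)
            + prm["ratio"] * np.exp(-0.5 * ((t - prm["mu2"]) / prm["s2"]) ** 2)
        )
        analytic = minimize_scalar(g, bounds=(prm["mu1"], prm["mu2"]), method="bounded").x
        assert abs(fid.notch_idx / 100.0 - analytic) <= 0.03

    def test_triangle_has_no_notch(self, cfg):
        fid = locate_fiducials(_triangle(), cfg)
        assert fid.notch_idx is None
        assert fid.peak_idx == 20

    def test_ordering_invariant(self, cfg):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            x, _ = two_gaussian_pulse(ratio=float(rng.uniform(0.1, 0.8)))
            fid = locate_fiducials(PulseSegment(x, 100.0, float(x[0])), cfg)
            assert fid.foot_idx < fid.peak_idx < fid.end_idx
            if fid.notch_idx is not None:
                assert fid.peak_idx <= fid.notch_idx < fid.end_idx

    def test_invalid_ordering_rejected(self):
        with pytest.raises(ValueError):
            Fiducials(foot_idx=5, peak_idx=2, end_idx=10)


class TestSecondDerivative:
    def test_sinusoid_matches_analytic(self, cfg):
        rate, f = 100.0, 2.0
        t = np.arange(0, 1, 1 / rate)
        p = PulseSegment(np.sin(2 * np.pi * f * t) + 2.0, rate, 2.0)
        d2 = second_derivative(p, cfg)
        true = -((2 * np.pi * f) ** 2) * np.sin(2 * np.pi * f * t)
        interior = slice(10, -10)
        assert np.max(np.abs(d2[interior] - true[interior])) < 0.05 * np.max(np.abs(true))

    def test_linear_ramp_is_flat(self, cfg):
        p = PulseSegment(np.linspace(0, 1, 50), 100.0, 0.0)
        assert np.max(np.abs(second_derivative(p, cfg))) < 1e-8

    def test_gaussian_extrema_locations(self, cfg):
        x, prm = two_gaussian_pulse()
        p = PulseSegment(x, 100.0, float(x[0]))
        d2 = second_derivative(p, cfg)
        tt = np.linspace(0, prm["duration"], 20001)
        g = prm["amp"] * (
            np.exp(-0.5 * ((tt - prm["mu1"]) / prm["s1"]) ** 2)
            + prm["ratio"] * np.exp(-0.5 * ((tt - prm["mu2"]) / prm["s2"]) ** 2)
        )
        d2a = np.gradient(np.gradient(g, tt), tt)
        edge = 5
        interior = np.arange(edge, x.size - edge)
        det_max = interior[np.argmax(d2[edge:-edge])] / 100.0
        det_min = interior[np.argmin(d2[edge:-edge])] / 100.0
        assert abs(det_max - tt[np.argmax(d2a)]) <= 0.03
        assert abs(det_min - tt[np.argmin(d2a)]) <= 0.03

    def test_too_short_pulse_rejected(self, cfg):
        with pytest.raises(ValueError):
            second_derivative(PulseSegment(np.zeros(10), 100.0, 0.0), cfg)


class TestComputeFeatures:
    def test_triangle_closed_form(self, cfg):
        p = _triangle()
        feats = compute_features(p, locate_fiducials(p, cfg), cfg)
        assert feats["amplitude"] == pytest.approx(1.0)
        assert feats["rise_time_s"] == pytest.approx(0.2)
        assert feats["decay_time_s"] == pytest.approx(0.4)
        assert feats["upslope_per_s"] == pytest.approx(5.0)
        assert feats["downslope_per_s"] == pytest.approx(-2.5)
        assert feats["pulse_width_s"] == pytest.approx(0.3)
        assert feats["auc"] == pytest.approx(0.3)
        assert feats["sys_area"] == pytest.approx(0.1)
        assert feats["dia_area"] == pytest.approx(0.2)
        assert feats["sys_dia_ratio"] == pytest.approx(0.5)

    def test_gaussian_auc_matches_erf_integral(self, cfg):
        x, prm = two_gaussian_pulse()
        p = PulseSegment(x, 100.0, float(x[0]))
        feats = compute_features(p, locate_fiducials(p, cfg), cfg)

        def gauss_int(mu, s, a, b):
            z = lambda v: (v - mu) / (s * np.sqrt(2))
            return s * np.sqrt(np.pi / 2) * (erf(z(b)) - erf(z(a)))

        analytic = (
            prm["amp"] * (gauss_int(prm["mu1"], prm["s1"], 0, prm["duration"])
            + prm["ratio"] * gauss_int(prm["mu2"], prm["s2"], 0, prm["duration"]))
            - x[0] * prm["duration"]
        )
        assert feats["auc"] == pytest.approx(analytic, rel=0.01)

    def test_area_conservation(self, cfg):
        for ratio in (0.2, 0.45, 0.7):
            x, _ = two_gaussian_pulse(ratio=ratio)
            p = PulseSegment(x, 100.0, float(x[0]))
            feats = compute_features(p, locate_fiducials(p, cfg), cfg)
            assert feats["sys_area"] + feats["dia_area"] == pytest.approx(
                feats["auc"], rel=1e-9
            )

    @settings(max_examples=30, deadline=None)
    @given(
        k=st.floats(0.05, 50.0, allow_nan=False),
        rise=st.integers(8, 40),
        decay=st.integers(8, 60),
    )
    def test_scaling_homogeneity(self, k, rise, decay):
        """Amplitude-based features are 1-homogeneous, time features and
        ratios invariant, under y -> k*y."""
        cfg = AnalysisConfig()
        rate = 100.0
        up = np.linspace(0, 1, rise + 1)
        down = np.linspace(1, 0, decay + 1)[1:]
        y = np.concatenate([up, down])
        f1 = compute_features(
            PulseSegment(y, rate, 0.0), Fiducials(0, rise, y.size - 1), cfg
        )
        f2 = compute_features(
            PulseSegment(k * y, rate, 0.0), Fiducials(0, rise, y.size - 1), cfg
        )
        for name in ("amplitude", "upslope_per_s", "downslope_per_s", "auc", "sys_area", "dia_area"):
            assert f2[name] == pytest.approx(k * f1[name], rel=1e-9)
        for name in ("pulse_width_s", "rise_time_s", "decay_time_s", "sys_dia_ratio", "sdppg_ratio"):
            assert f2[name] == pytest.approx(f1[name], rel=1e-6)

    @settings(max_examples=30, deadline=None)
    @given(rise=st.integers(8, 40), decay=st.integers(8, 60), amp=st.floats(0.5, 3.0))
    def test_time_reversal_swaps_rise_and_decay(self, rise, decay, amp):
        cfg = AnalysisConfig()
        rate = 100.0
        y = amp * np.concatenate([np.linspace(0, 1, rise + 1), np.linspace(1, 0, decay + 1)[1:]])
        fwd = compute_features(
            PulseSegment(y, rate, 0.0), Fiducials(0, rise, y.size - 1), cfg
        )
        rev = compute_features(
            PulseSegment(y[::-1].copy(), rate, 0.0),
            Fiducials(0, decay, y.size - 1),
            cfg,
        )
        assert rev["rise_time_s"] == pytest.approx(fwd["decay_time_s"])
        assert rev["decay_time_s"] == pytest.approx(fwd["rise_time_s"])
        assert rev["upslope_per_s"] == pytest.approx(-fwd["downslope_per_s"])
        assert rev["downslope_per_s"] == pytest.approx(-fwd["upslope_per_s"])
        assert rev["amplitude"] == pytest.approx(fwd["amplitude"])
        assert rev["auc"] == pytest.approx(fwd["auc"], rel=1e-9)
        assert rev["pulse_width_s"] == pytest.approx(fwd["pulse_width_s"], abs=1e-9)

    def test_flat_tail_zero_dia_area_rejected(self, cfg):
        y = np.concatenate([np.linspace(0, 1, 21), np.linspace(1, 0, 11)[1:], np.zeros(20)])
        # boundary at the very end -> dia_area 0
        with pytest.raises(DegeneratePulseError):
            compute_features(
                PulseSegment(y, 100.0, 0.0), Fiducials(0, 20, y.size - 1, notch_idx=y.size - 2), cfg
            )


class TestPulseRecords:
    def test_rise_time_tracks_commanded_morphology(self, cfg):
        """Detected per-pulse rise time correlates (r > 0.9) with the
        generator's commanded systolic-peak time across a wide sweep."""
        rng = np.random.default_rng(11)
        rate, ibi = 100.0, 0.6
        beats = np.arange(0.0, 240.0, ibi)
        mu1 = np.linspace(0.11, 0.22, beats.size)  # commanded rise times
        n = int(245.0 * rate)
        x = np.zeros(n)
        for bt, m in zip(beats, mu1):
            i0, i1 = int(bt * rate), min(int((bt + ibi) * rate), n)
            tau = (np.arange(i0, i1) - i0) / rate
            x[i0:i1] += np.exp(-0.5 * ((tau - m) / 0.045) ** 2) + 0.35 * np.exp(
                -0.5 * ((tau - m - 0.22) / 0.09) ** 2
            )
        x += 0.002 * rng.normal(size=n)
        recs = pulse_records(SampledSignal(x, rate), cfg)
        assert len(recs) > 200
        t_feet = np.array([t for t, _ in recs])
        rises = np.array([f["rise_time_s"] for _, f in recs])
        commanded = mu1[np.argmin(np.abs(t_feet[:, None] - beats[None, :]), axis=1)]
        assert np.corrcoef(rises, commanded)[0, 1] > 0.9
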