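"""Artifact detection, synchronous removal, filtering and normalization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal as sps

from nicp.config import AnalysisConfig
from nicp.core import SampledSignal, SessionRecording
from nicp.preprocessing import (
    ArtifactMask,
    DCFloorError,
    REASON_SATURATION,
    detect_artifacts,
    extract_ac,
    extract_dc,
    normalize,
    preprocess_session,
    remove_synchronous,
)


def _sin(freq, duration=60.0, rate=100.0, amp=1.0, offset=0.0):
    t = np.arange(0, duration, 1.0 / rate)
    return SampledSignal(offset + amp * np.sin(2 * np.pi * freq * t), rate)


class TestDetectArtifacts:
    def test_clean_sinusoid_unflagged(self, cfg):
        mask = detect_artifacts(_sin(1.0), cfg)
        assert mask.bad.sum() == 0

    def test_saturation_plateau_flagged(self, cfg):
        sig = _sin(1.0)
        sig.values[3000:3200] = sig.values.max()  # 2-s rail plateau
        mask = detect_artifacts(sig, cfg)
        assert mask.bad[3000:3200].all()
        assert (mask.reasons[3000:3200] == REASON_SATURATION).all()
        # flagging stays local: nothing beyond plateau + dilation + one
        # movement-detector window
        assert not mask.bad[: 3000 - 250].any()
        assert not mask.bad[3200 + 250 :].any()

    def test_movement_burst_flagged(self, cfg):
        sig = _sin(1.0)
        rng = np.random.default_rng(0)
        sig.values[2000:2100] += rng.normal(0, 20.0, 100)  # 1-s burst, 20x amplitude
        mask = detect_artifacts(sig, cfg)
        assert mask.bad[2000:2100].mean() >= 0.95

    def test_injected_artifacts_recovered(self, cfg, noisy_session):
        """>=95% of injected artifact samples flagged, <=5% of clean samples
        flagged; "clean" excludes the detector's structural spillover around
        each event (one 1-s analysis window plus the 0.5-s dilation)."""
        rec, truth = noisy_session
        mask = detect_artifacts(rec.ppg_distal, cfg)
        n, rate = len(rec), rec.rate
        injected = np.zeros(n, dtype=bool)
        guard = np.zeros(n, dtype=bool)
        for s, e, _kind in truth.artifact_intervals:
            injected[int(s * rate) : int(e * rate)] = True
            guard[max(0, int((s - 1.6) * rate)) : int((e + 1.6) * rate)] = True
        assert mask.bad[injected].mean() >= 0.95
        assert mask.bad[~guard].mean() <= 0.05

    def test_too_short_signal_rejected(self, cfg):
        with pytest.raises(ValueError):
            detect_artifacts(SampledSignal(np.zeros(50), 100.0), cfg)


def _mask(n, bad_slice=None):
    bad = np.zeros(n, dtype=bool)
    if bad_slice is not None:
        bad[bad_slice] = True
    return ArtifactMask(bad=bad, reasons=np.zeros(n, dtype=np.int8))


def _rec(n=6000, rate=100.0):
    rng = np.random.default_rng(1)
    return SessionRecording(
        patient_id="x",
        ppg_distal=SampledSignal(rng.normal(size=n), rate),
        icp=SampledSignal(np.linspace(10, 20, n), rate),
    )


class TestRemoveSynchronous:
    def test_all_clean_identity(self, cfg):
        rec = _rec()
        spans = remove_synchronous(rec, _mask(6000), cfg)
        assert len(spans) == 1
        assert spans[0].start_index == 0 and len(spans[0].ppg) == 6000

    def test_masked_middle_cuts_icp_identically(self, cfg):
        rec = _rec()
        spans = remove_synchronous(rec, _mask(6000, slice(1000, 2000)), cfg)
        assert [(s.start_index, len(s.ppg)) for s in spans] == [(0, 1000), (2000, 4000)]
        for s in spans:
            assert len(s.ppg) == len(s.icp)
            np.testing.assert_array_equal(
                s.icp.values, rec.icp.values[s.start_index : s.start_index + len(s.icp)]
            )

    def test_short_spans_discarded(self, cfg):
        rec = _rec()
        bad = np.zeros(6000, dtype=bool)
        for start in range(500, 6000, 1000):  # alternating 5-s clean / 5-s bad
            bad[start : start + 500] = True
        assert remove_synchronous(rec, ArtifactMask(bad, np.zeros(6000, np.int8)), cfg) == []


class TestFilters:
    def test_bandpass_rejects_dc(self, cfg):
        out = extract_ac(SampledSignal(np.full(6000, 5.0), 100.0), cfg)
        assert np.max(np.abs(out.values)) < 1e-6 * 5.0

    @pytest.mark.parametrize("freq", [1.2, 0.1, 5.0, 15.0])
    def test_bandpass_gain_matches_design_response(self, cfg, freq):
        """Measured sinusoid gain equals |H|^2 of the designed Butterworth
        (forward-backward squares the magnitude response)."""
        sos = sps.butter(2, cfg.ac_band_hz, btype="bandpass", fs=100.0, output="sos")
        (_, h) = sps.sosfreqz(sos, worN=[2 * np.pi * freq / 100.0])
        expected = np.abs(h[0]) ** 2
        out = extract_ac(_sin(freq, duration=120.0), cfg).values
        mid = out[3000:9000]  # steady-state interior
        measured = (mid.max() - mid.min()) / 2
        assert measured == pytest.approx(expected, rel=0.02, abs=1e-4)

    def test_subband_sinusoid_strongly_attenuated(self, cfg):
        out = extract_ac(_sin(0.1, duration=120.0), cfg).values
        assert (out[3000:9000].max() - out[3000:9000].min()) / 2 < 0.1

    def test_lowpass_unity_dc_gain(self, cfg):
        out = extract_dc(SampledSignal(np.full(6000, 5.0), 100.0), cfg)
        np.testing.assert_allclose(out.values, 5.0, rtol=1e-9)

    def test_lowpass_recovers_offset_under_pulse(self, cfg):
        sig = _sin(1.0, duration=120.0, offset=3.0)
        out = extract_dc(sig, cfg).values[3000:9000]
        assert np.max(np.abs(out - 3.0)) < 0.05  # ripple < 5% of unit amplitude

    def test_lowpass_tracks_slow_drift(self, cfg):
        t = np.arange(0, 300, 0.01)
        drift = 2.0 * np.sin(2 * np.pi * 0.01 * t)
        sig = SampledSignal(10 + drift + np.sin(2 * np.pi * 1.0 * t), 100.0)
        out = extract_dc(sig, cfg).values
        inner = slice(3000, -3000)
        assert np.corrcoef(out[inner], drift[inner])[0, 1] > 0.99

    def test_rate_below_nyquist_of_upper_cutoff_rejected(self, cfg):
        with pytest.raises(ValueError):
            extract_ac(SampledSignal(np.zeros(300), 15.0), cfg)

    @settings(max_examples=20, deadline=None)
    @given(
        a=st.floats(-3, 3, allow_nan=False),
        b=st.floats(-3, 3, allow_nan=False),
        seed=st.integers(0, 2**16),
    )
    def test_filtering_is_linear(self, a, b, seed):
        cfg = AnalysisConfig()
        rng = np.random.default_rng(seed)
        x = SampledSignal(rng.normal(size=2000), 100.0)
        y = SampledSignal(rng.normal(size=2000), 100.0)
        combo = SampledSignal(a * x.values + b * y.values, 100.0)
        lhs = extract_ac(combo, cfg).values
        rhs = a * extract_ac(x, cfg).values + b * extract_ac(y, cfg).values
        np.testing.assert_allclose(lhs, rhs, atol=1e-8)


class TestNormalize:
    def test_constant_ratio(self, cfg):
        ac = SampledSignal(np.full(100, 0.5), 100.0)
        dc = SampledSignal(np.full(100, 5.0), 100.0)
        np.testing.assert_allclose(normalize(ac, dc, cfg).values, 1.0)

    def test_zero_ac_gives_zero(self, cfg):
        ac = SampledSignal(np.zeros(100), 100.0)
        dc = SampledSignal(np.full(100, 5.0), 100.0)
        np.testing.assert_allclose(normalize(ac, dc, cfg).values, 0.0)

    def test_dc_floor_rejects_span(self, cfg):
        ac = SampledSignal(np.ones(100), 100.0)
        dcv = np.full(100, 5.0)
        dcv[50] = 1e-6
        with pytest.raises(DCFloorError):
            normalize(ac, SampledSignal(dcv, 100.0), cfg)

    @settings(max_examples=20, deadline=None)
    @given(k=st.floats(0.01, 100.0, allow_nan=False), seed=st.integers(0, 2**16))
    def test_gain_invariance_end_to_end(self, k, seed):
        """Scaling the raw light intensity by k leaves normalized PPG unchanged."""
        cfg = AnalysisConfig()
        rng = np.random.default_rng(seed)
        t = np.arange(0, 30, 0.01)
        raw = 100 + np.sin(2 * np.pi * 1.2 * t) + 0.1 * rng.normal(size=t.size)
        out = []
        for scale in (1.0, k):
            sig = SampledSignal(scale * raw, 100.0)
            norm = normalize(extract_ac(sig, cfg), extract_dc(sig, cfg), cfg)
            out.append(norm.values)
        np.testing.assert_allclose(out[0], out[1], atol=1e-9, rtol=1e-7)


class TestPreprocessSession:
    def test_alignment_preserved_in_every_span(self, cfg, noisy_session):
        rec, _ = noisy_session
        segments, _ = preprocess_session(rec, cfg)
        assert segments
        for seg in segments:
            assert len(seg.ppg_norm) == len(seg.icp) == len(seg.ppg_dc)

    def test_retained_fraction_matches_injected_corruption(self, cfg, noisy_session):
        rec, truth = noisy_session
        _, report = preprocess_session(rec, cfg)
        p = truth.artifact_seconds / rec.ppg_distal.duration_s
        assert 1 - p - 0.05 <= report.retained_fraction <= 1 - p + 0.05

    def test_denoising_improves_in_band_snr(self, cfg, noisy_session):
        rec, _ = noisy_session
        _, report = preprocess_session(rec, cfg)
        assert report.snr_after_db > report.snr_before_db
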