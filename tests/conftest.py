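import numpy as np
import pytest

from nicp.config import AnalysisConfig
from nicp.core import SampledSignal
from nicp.simulate import SimParams, simulate_patient


@pytest.fixture(scope="session")
def cfg() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture(scope="session")
def rate() -> float:
    return 100.0


@pytest.fixture(scope="session")
def clean_session():
    """10 min of artifact- and noise-free constant-ICP recording + truth."""
    params = SimParams(
        duration_s=600.0,
        icp_sd_mmhg=0.0,
        n_hypertension_events=0,
        noise_sd=0.0,
        artifact_fraction=0.0,
        seed=3,
    )
    return simulate_patient(params, patient_id="clean")


@pytest.fixture(scope="session")
def noisy_session():
    """30 min of default-condition recording with injected artifacts."""
    params = SimParams(duration_s=1800.0, seed=7)
    return simulate_patient(params, patient_id="noisy")


def two_gaussian_pulse(
    rate: float = 100.0,
    amp: float = 1.0,
    mu1: float = 0.15,
    s1: float = 0.045,
    mu2: float = 0.40,
    s2: float = 0.07,
    ratio: float = 0.45,
    duration: float = 0.85,
) -> tuple[np.ndarray, dict]:
    """Analytic two-Gaussian pulse and its parameters (test oracle input)."""
    tau = np.arange(0.0, duration + 1e-12, 1.0 / rate)
    x = amp * (
        np.exp(-0.5 * ((tau - mu1) / s1) ** 2) + ratio * np.exp(-0.5 * ((tau - mu2) / s2) ** 2)
    )
    return x, dict(amp=amp, mu1=mu1, s1=s1, mu2=mu2, s2=s2, ratio=ratio, duration=duration)


def pulse_train(
    beat_times: np.ndarray,
    duration_s: float,
    rate: float = 100.0,
    amplitudes: np.ndarray | None = None,
) -> SampledSignal:
    """Clean two-Gaussian pulse train on given beat onsets."""
    n = int(duration_s * rate)
    x = np.zeros(n)
    amplitudes = np.ones(len(beat_times)) if amplitudes is None else amplitudes
    bounds = np.append(beat_times, duration_s)
    for i, bt in enumerate(beat_times):
        i0, i1 = int(bt * rate), min(int(bounds[i + 1] * rate), n)
        tau = (np.arange(i0, i1) - i0) / rate
        x[i0:i1] += amplitudes[i] * (
            np.exp(-0.5 * ((tau - 0.15) / 0.045) ** 2)
            + 0.35 * np.exp(-0.5 * ((tau - 0.37) / 0.09) ** 2)
        )
    return SampledSignal(x, rate)
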