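import numpy as np
import pytest

from gatebeat.synth import (
    CardiacSimParams,
    GatingSimParams,
    simulate_ecg_session,
    synth_eeg_session,
)


@pytest.fixture(scope="session")
def modulated_ecg():
    """5-min ECG with LF+HF rate modulation, respiration at 0.25 Hz, 2% noise."""
    params = CardiacSimParams(a_lf=0.05, a_hf=0.03, noise_sd=0.02, seed=7)
    return simulate_ecg_session(params)


@pytest.fixture(scope="session")
def clean_session():
    """Noise-free paired-click session, g = 0.5: recovery should be exact."""
    params = GatingSimParams(
        n_pairs=20, true_ratio=0.5, background_rms=0.0, artifact_rate=0.0, seed=11
    )
    return synth_eeg_session(params)


@pytest.fixture(scope="session")
def noisy_session():
    """Default-background session with injected artifacts, g = 0.5."""
    params = GatingSimParams(n_pairs=40, true_ratio=0.5, artifact_rate=0.15, seed=13)
    return synth_eeg_session(params)


@pytest.fixture
def rng():
    return np.random.default_rng(20231020)
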