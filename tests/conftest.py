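import numpy as np
import pytest

from tremorscore.features import feature_matrix
from tremorscore.simulate import DEFAULT_PROFILES, SimulationConfig, simulate_dataset

MASTER_SEED = 20170909  # fixed for reproducible synthetic fixtures


@pytest.fixture(scope="session")
def balanced_dataset():
    """20 recordings per class with default severity profiles."""
    cfg = SimulationConfig(seed=MASTER_SEED)
    recs, labels = simulate_dataset([20, 20, 20, 20, 20], cfg, seed=MASTER_SEED)
    return recs, labels


@pytest.fixture(scope="session")
def balanced_features(balanced_dataset):
    recs, labels = balanced_dataset
    return feature_matrix(recs, labels)


@pytest.fixture(scope="session")
def class_recording():
    """One fixed-seed recording per severity class."""
    cfg = SimulationConfig(seed=MASTER_SEED)

    def make(cls: int, seed: int = 7):
        from tremorscore.simulate import simulate_recording

        return simulate_recording(DEFAULT_PROFILES[cls], cfg, seed=seed)

    return make


def sinusoid(freq_hz: float, fs: float = 125.0, duration_s: float = 60.0, amplitude: float = 1.0):
    t = np.arange(int(round(duration_s * fs))) / fs
    return amplitude * np.sin(2 * np.pi * freq_hz * t), t


def demodulated_amplitude(x, freq_hz: float, fs: float = 125.0, settle_s: float = 10.0):
    """Steady-state amplitude of the ``freq_hz`` component, ignoring edges.

    Quadrature demodulation isolates the tone from filter edge transients,
    so even deep-stopband gains are measurable.
    """
    n = int(settle_s * fs)
    seg = np.asarray(x)[n:-n]
    t = np.arange(len(seg)) / fs
    return 2 * abs(np.mean(seg * np.exp(-2j * np.pi * freq_hz * t)))
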