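import numpy as np
import pytest

from ohcsync.config import SimulationConfig, WaveSpec


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_config():
    """A short, small recording used by several round-trip tests."""
    return SimulationConfig(n_cells=9, n_frames=400, field_um=125.0,
                            noise_sd=0.0, bleach_tau_s=0.0, seed=7,
                            wave_schedule=())


@pytest.fixture(scope="session")
def single_wave():
    return WaveSpec(onset_s=6.0, extent_um=80.0, center_um=91.0,
                    amplitude=1.0, duration_s=5.0)
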