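import numpy as np
import pytest

from envtrack import synthdata as sd
from envtrack import trf
from envtrack.envelope import FilterbankSpec, multiband_envelope


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_config():
    """Reduced-scale simulation config used across TRF/synth tests."""
    return sd.SimulationConfig(
        n_tracks=4,
        track_duration_s=8.0,
        n_channels=4,
        snr_db=0.0,
        seed=7,
        n_bands=4,
        f_low=250.0,
        f_high=4000.0,
    )


@pytest.fixture(scope="session")
def small_window():
    return trf.LagWindow(fs=128.0)


@pytest.fixture(scope="session")
def small_envs(small_config, small_window):
    """Envelope features for a fixed small stimulus set (shared across tests)."""
    rng = np.random.default_rng(99)
    stimuli = [
        sd.make_syllabic_stimulus(
            small_config.track_duration_s, small_config.audio_fs, 4.5, rng
        )
        for _ in range(small_config.n_tracks)
    ]
    envs = [
        multiband_envelope(s, small_config.filterbank, fs_out=small_config.eeg_fs)
        for s in stimuli
    ]
    return stimuli, envs


@pytest.fixture(scope="session")
def small_gram(small_envs, small_window):
    _, envs = small_envs
    return trf.DesignGram(trf.prepare_designs(envs, small_window))
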