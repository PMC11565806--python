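import numpy as np
import pytest

from fnirsinc import synthetic_data as sd


@pytest.fixture(scope="session")
def probe():
    return sd.generate_probe()


@pytest.fixture(scope="session")
def sim_config():
    return sd.SimulationConfig(seed=0)


@pytest.fixture(scope="session")
def cohort(sim_config):
    return sd.generate_participants(30, sim_config)


@pytest.fixture()
def clean_config():
    """Noise-free, symmetric-gain config for exact-value checks."""
    return sd.SimulationConfig(
        seed=0, noise_floor_raw=0.0, cardiac_rel_amplitude=0.0,
        systemic_rel_amplitude=0.0, wavelength_gains=(1.0, 1.0),
        channel_log10_sd=0.0,
    )


def make_recording(data, fs=10.2, power=None, channels=None):
    """Wrap a (n_ch, 2, n_t) array as an IntensityRecording with dummy
    channel metadata."""
    data = np.asarray(data, dtype=float)
    if channels is None:
        channels = [sd.Channel(f"S{i+1}", f"D{i+1}", 30.0, "long", "side",
                               "right") for i in range(data.shape[0])]
    return sd.IntensityRecording(data=data, fs=fs, channels=channels,
                                 source_power_pct=power)
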