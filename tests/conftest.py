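import numpy as np
import pytest

import ehgkit as ek

FS = 20.0


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_config():
    """Short records keep the synthetic fixtures fast."""
    return ek.SimulationConfig(n_P=3, n_T=3, duration_s=240.0, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    records, manifest = ek.generate_cohort(
        ek.preterm_profile(), ek.term_profile(), small_config)
    return records, manifest


@pytest.fixture(scope="session")
def tone_window():
    """One 120-s window of a unit 0.65-Hz tone at 20 Hz."""
    t = np.arange(2400) / FS
    return np.sin(2 * np.pi * 0.65 * t)
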