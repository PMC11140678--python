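import numpy as np
import pytest

from cortrack.synthetic import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def tone_1khz():
    """500 ms pure 1 kHz tone at 16 kHz."""
    from cortrack.features import Waveform

    t = np.arange(int(0.5 * 16_000)) / 16_000
    return Waveform(np.sin(2 * np.pi * 1000 * t))


@pytest.fixture(scope="session")
def noisefree_cohort():
    """Small noise-free cohort: the well-conditioned inversion regime."""
    spec = CohortSpec(n_per_group=1, n_stimuli=12, n_sensors=8, seed=31)
    return generate_cohort(spec, deficit_factor=1.0, noise_sd=0.0)


@pytest.fixture(scope="session")
def small_noisy_cohort():
    """Two small groups with a strong late-lag deficit."""
    spec = CohortSpec(n_per_group=2, n_stimuli=8, n_sensors=6, seed=32)
    return generate_cohort(spec, deficit_factor=0.3)
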