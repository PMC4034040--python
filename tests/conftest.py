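import numpy as np
import pytest

import erptopo as et


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def montage16():
    return et.make_montage(16, seed=0)


@pytest.fixture(scope="session")
def templates4(montage16):
    return et.make_templates(4, montage16, rng=0)


@pytest.fixture(scope="session")
def small_study():
    """A small two-condition study with the default serial-shift effect."""
    design = et.SimulationDesign(
        n_electrodes=24, n_subjects=6, n_trials=4, noise_rms_uv=1.0
    )
    return et.simulate_study(design, seed=42, keep_trials=True)


@pytest.fixture(scope="session")
def small_averages(small_study):
    return et.subject_averages(small_study)
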