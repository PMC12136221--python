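import numpy as np
import pytest

from hemiasym.simulate import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """40-subject, 120-vertex cohort with default planted structure."""
    config = SimulationConfig(n_subjects=40, n_vertices=120, seed=7)
    return generate_cohort(config)


@pytest.fixture(scope="session")
def zero_noise_cohort():
    """Noiseless, coupling-free cohort: the asymmetry index inverts the
    generative model exactly."""
    base = SimulationConfig(n_subjects=5, n_vertices=120, seed=3)
    config = base.replace(
        vertex_noise_sd=0.0, subject_noise_sd=0.0, accuracy_noise_sd=0.0,
        coupling=base.coupling * 0.0)
    return generate_cohort(config)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
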