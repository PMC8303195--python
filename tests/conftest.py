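import numpy as np
import pytest

from irisilo import Template


def random_template(rng, shape=(8, 128), mask_p=0.0):
    """A uniform random template; mask bits invalid independently at mask_p."""
    phase = rng.integers(0, 2, shape, dtype=np.uint8)
    mask = None
    if mask_p > 0:
        mask = (rng.random(shape) >= mask_p).astype(np.uint8)
    return Template(phase, mask)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_template(rng):
    return random_template(rng, shape=(4, 6))


@pytest.fixture(scope="session")
def population():
    """Shared synthetic population: 60 subjects, 3 templates each."""
    from irisilo import PopulationConfig, generate_population

    config = PopulationConfig(
        n_subjects=60, templates_per_subject=3, master_seed=11
    )
    return config, generate_population(config)
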