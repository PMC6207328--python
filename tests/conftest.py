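import numpy as np
import pytest

from rodmotion.synthetic import (ImagingConfig, generate_population,
                                 simulate_movie)


@pytest.fixture(scope="session")
def small_movie():
    """A deterministic 12-cell TIRF movie with ground truth, shared across
    tests that only read it."""
    cells = generate_population(n_cells=12, emitter_density=3.0, seed=42)
    config = ImagingConfig(seed=42)
    movie, truth = simulate_movie(cells, config)
    return cells, config, movie, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
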