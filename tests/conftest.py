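import numpy as np
import pytest

from gmopanel import GeneratorConfig, generate_matrix, toy_matrix


@pytest.fixture
def toy():
    return toy_matrix()


def random_small_matrix(seed, max_events=12, max_elements=8, min_events=2):
    """Seeded random matrix small enough for world-enumeration oracles."""
    rng = np.random.default_rng(seed)
    n_events = int(rng.integers(min_events, max_events + 1))
    n_elements = int(rng.integers(1, max_elements + 1))
    cfg = GeneratorConfig(
        n_events=n_events,
        n_elements=n_elements,
        presence_density=float(rng.uniform(0.1, 0.6)),
        prior_range=(0.001, float(rng.uniform(0.05, 0.6))),
        n_species=int(rng.integers(1, 4)),
        unknown_rate=float(rng.choice([0.0, 0.1])),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    return generate_matrix(cfg)
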