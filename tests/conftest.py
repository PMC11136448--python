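import numpy as np
import pytest

import gatescribe as g


@pytest.fixture(scope="session")
def small_dataset():
    """4-type, 6-marker synthetic dataset at 6 sd separation (n=4000)."""
    spec = g.standard_spec(n_cells=4000, seed=11)
    matrix, labels = g.generate_dataset(spec)
    return spec, matrix, labels


@pytest.fixture
def two_component_values():
    rng = np.random.default_rng(7)
    return np.concatenate(
        [rng.normal(0.0, 0.25, 1000), rng.normal(5.0, 0.25, 1000)]
    )
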