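import numpy as np
import pandas as pd
import pytest

from tractometry.synthetic import CohortSpec, generate_atlas, generate_cohort
from tractometry.tensor import make_scheme


@pytest.fixture(scope="session")
def scheme():
    """1 b0 + 30 well-spread directions at b = 1000 s/mm^2."""
    return make_scheme(n_directions=30, bvalue=1000.0, n_b0=1)


@pytest.fixture(scope="session")
def small_registry():
    """A three-bundle registry for fast unit tests."""
    return pd.DataFrame(
        {
            "index": [1, 2, 3],
            "abbreviation": ["B1", "B2", "B3"],
            "name": ["bundle one", "bundle two", "bundle three"],
            "n_fibers": [6, 5, 4],
        }
    )


@pytest.fixture(scope="session")
def small_atlas(small_registry):
    return generate_atlas(registry=small_registry, seed=7)


@pytest.fixture(scope="session")
def small_spec():
    return CohortSpec(
        group_sizes={"control": 10, "bvFTD": 8, "EOAD": 8},
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec, small_registry):
    return generate_cohort(small_spec, registry=small_registry)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
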