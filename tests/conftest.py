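import numpy as np
import pytest

from medipspike.catalog import (
    assign_amounts,
    build_catalog,
    generate_catalog_sequences,
)


@pytest.fixture(scope="session")
def catalog52():
    """Final 52-fragment catalog with generated sequences and known
    amounts for an equimolar-within-length-pool 0.01 ng pool."""
    c = build_catalog(include_failed=False, pool_mass_ng=0.01)
    c = generate_catalog_sequences(c, seed=11)
    return assign_amounts(c, 0.01, "per-length-pool")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
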