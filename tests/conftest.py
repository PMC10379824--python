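import numpy as np
import pytest

from marinerscan import CanonicalProfile, make_canonical_element, plant_copies


@pytest.fixture(scope="session")
def profile() -> CanonicalProfile:
    return CanonicalProfile()


@pytest.fixture(scope="session")
def canonical(profile):
    """Canonical element built under a fixed seed, with its ground truth."""
    return make_canonical_element(profile, 1)


@pytest.fixture(scope="session")
def planted_genome(profile):
    """One genome with three clean canonical copies plus truth."""
    return plant_copies(30000, profile, 3, seed=7, genome_id="g1", species="sp1")


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
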