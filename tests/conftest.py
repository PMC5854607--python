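import numpy as np
import pytest

from strainsieve import simulate as sim


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_genome(rng):
    return sim.random_genome(10_000, rng, id="chr")


@pytest.fixture(scope="session")
def strain_pair():
    """A small two-strain community shared by binning tests."""
    cfg = sim.StrainSimConfig(
        backbone_len=60_000,
        n_unique_regions_per_strain=3,
        unique_region_len=4_000,
        n_inversions=1,
        n_relocations=1,
        total_depth=80.0,
        seed=7,
    )
    return cfg, sim.simulate_strain_pair(cfg)
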