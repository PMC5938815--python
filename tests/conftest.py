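import numpy as np
import pytest

from adasmooth import build_neighbor_ordering, generate_region, run_replications
from adasmooth.geography import AgeStratum, StudyRegion
from adasmooth.reference import default_strata_specs


@pytest.fixture(scope="session")
def standard_region():
    """Scaled-down standard fixture: 400 zones, the four published strata."""
    return generate_region(400, default_strata_specs(400), layout="grid", seed=11)


@pytest.fixture(scope="session")
def standard_replicates(standard_region):
    """100 replicate case sets plus baseline rates on the standard fixture."""
    return run_replications(standard_region, 100, base_seed=1)


@pytest.fixture(scope="session")
def standard_ordering(standard_region):
    return build_neighbor_ordering(standard_region)


@pytest.fixture
def small_region():
    """20 zones, 2 strata, small populations; cheap enough for brute-force checks."""
    rng = np.random.default_rng(42)
    n = 20
    pops_a = rng.integers(50, 500, n)
    pops_b = rng.integers(10, 200, n)
    return StudyRegion(
        zone_ids=[f"Z{i:02d}" for i in range(1, n + 1)],
        centroids=rng.uniform(0, 10, (n, 2)),
        populations={"A": pops_a, "B": pops_b},
        strata=[
            AgeStratum("A", 500.0, int(pops_a.sum())),
            AgeStratum("B", 2000.0, int(pops_b.sum())),
        ],
    )


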