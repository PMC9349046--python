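import numpy as np
import pytest

import genomepop as gp


@pytest.fixture
def toy_segmentation():
    """Two diploid chromosomes of 3 bins each (H = 6, N = 12)."""
    return gp.segment_genome({"chr1": 600_000, "chr2": 600_000}, 200_000)


@pytest.fixture
def sphere_geometry():
    return gp.NuclearGeometry.sphere(3000.0)


@pytest.fixture
def ellipsoid_geometry():
    return gp.NuclearGeometry((3000.0, 2500.0, 2000.0))


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_population(toy_segmentation, sphere_geometry):
    """A relaxed 4-structure population of the toy genome (deterministic)."""
    r0 = gp.bead_radius_from_occupancy(sphere_geometry, toy_segmentation.N, 0.1)
    beads = gp.BeadGeometry(r0, 0.1)
    return gp.init_population(toy_segmentation, sphere_geometry, beads, S=4, seed=7)
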