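import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from canolux.config import GUAVA_SITE, GUAVA_SKY
from canolux.hemiphoto import CrownStructure, SkyGrid, binarize, crown_structure
from canolux.synth import CrownTruth, StudyDesign, gen_canopy_mask, gen_study

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def site():
    return GUAVA_SITE


@pytest.fixture(scope="session")
def sky():
    return GUAVA_SKY


def crown_from_gap(gap, grid: SkyGrid = SkyGrid()) -> CrownStructure:
    """CrownStructure built directly from a gap-fraction value or
    (n_zenith, n_azimuth) array — exact geometry, no image noise."""
    g = np.broadcast_to(np.asarray(gap, dtype=float),
                        (grid.n_zenith, grid.n_azimuth))
    rings = np.repeat(np.arange(grid.n_zenith), grid.n_azimuth)
    slices = np.tile(np.arange(grid.n_azimuth), grid.n_zenith)
    df = pd.DataFrame({
        "ring": rings, "slice": slices,
        "gap_fraction": g[rings, slices],
        "clumping": 1.0,
        "used": ~np.isin(rings, list(grid.discarded_rings)),
    })
    return CrownStructure(segments=df, grid=grid, element_width=2.0)


@pytest.fixture(scope="session")
def random_crown_structure():
    """Analyzed random (Poisson) canopy image at G = 0.3."""
    truth = CrownTruth(ring_gap=np.full(10, 0.3),
                       ring_cluster_scale=np.zeros(10))
    image, table = gen_canopy_mask(truth, image_size=481, seed=11)
    return crown_structure(binarize(image)), table


@pytest.fixture(scope="session")
def small_study():
    """A 3-tree synthetic study (reduced raster) for pipeline tests."""
    return gen_study(StudyDesign(n_trees=3, image_size=361), seed=5)
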