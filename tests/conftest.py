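import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

import eudgate as eg
from eudgate.pipeline import cohort_features


@pytest.fixture(scope="session")
def reference_cohort():
    """Full-size synthetic cohort at the default study conditions."""
    return eg.generate_cohort(eg.CohortConfig(seed=0))


@pytest.fixture(scope="session")
def reference_features(reference_cohort):
    return cohort_features(reference_cohort)


@pytest.fixture(scope="session")
def mini_cohort():
    """Small, fast cohort for structural tests."""
    cfg = eg.CohortConfig(
        n_patients=3,
        fractions_range=(4, 6),
        ctv_volume_range=(50.0, 80.0),
        grid_shape=(40, 40, 40),
        use_table_values=False,
        seed=7,
    )
    return cfg, eg.generate_cohort(cfg)


@pytest.fixture
def small_spec():
    return eg.GridSpec((24, 24, 24), (2.0, 2.0, 2.0))


def random_blob_mask(spec, rng, threshold=55.0):
    """Random nonempty smooth blob on a grid (for distance/warp oracles)."""
    noise = gaussian_filter(rng.standard_normal(spec.shape), sigma=2.0)
    mask = noise > np.percentile(noise, threshold)
    if not mask.any():
        mask.flat[int(rng.integers(mask.size))] = True
    return eg.StructureMask(spec, mask)


def brute_force_directed_hausdorff(ctv_plan, ctv_i):
    """O(N^2) oracle: max over ctv_i voxels of min distance to ctv_plan."""
    from scipy.spatial.distance import cdist

    a = ctv_plan.grid.voxel_centers(ctv_plan.values)
    b = ctv_i.grid.voxel_centers(ctv_i.values)
    d = cdist(b, a).min(axis=1)
    i = int(np.argmax(d))  # first occurrence = lowest linear index in b
    return float(d[i]), b[i]
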