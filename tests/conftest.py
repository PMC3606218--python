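import numpy as np
import pytest

from tractconn.atlas import connectome_atlas
from tractconn.phantoms import CohortConfig, PhantomSpec, make_tensor_phantom, simulate_cohort
from tractconn.tracking import TrackingParams, track_streamlines


@pytest.fixture(scope="session")
def atlas70():
    return connectome_atlas()


@pytest.fixture(scope="session")
def slab_volume():
    spec = PhantomSpec(
        shape=(24, 12, 12),
        geometry="straight_slab",
        geometry_params={"thickness": 16.0, "half_width": 3.0},
        fa_target=0.7,
    )
    return make_tensor_phantom(spec)


@pytest.fixture(scope="session")
def slab_tractogram(slab_volume):
    return track_streamlines(slab_volume, TrackingParams())


@pytest.fixture(scope="session")
def null_cohort(atlas70):
    """No group effect, no planted edges: groups exchangeable."""
    cfg = CohortConfig(seed=42, global_ratio=1.0, n_per_group=15)
    return simulate_cohort(cfg, atlas70)


@pytest.fixture(scope="session")
def small_cohort(atlas70):
    cfg = CohortConfig(seed=7, n_per_group=20)
    return simulate_cohort(cfg, atlas70)


def brute_force_edge_scan(mean_matrix: np.ndarray, diagonal_band: int):
    """Independent oracle: sort present edges, scan one by one from the
    lowest value, stop at the first edge farther than ``diagonal_band``
    from the diagonal; exclude everything strictly below its value."""
    n = mean_matrix.shape[0]
    edges = [
        (mean_matrix[i, j], i, j)
        for i in range(n)
        for j in range(i, n)
        if mean_matrix[i, j] > 0
    ]
    edges.sort()
    threshold = edges[-1][0]
    for v, i, j in edges:
        if abs(i - j) > diagonal_band:
            threshold = v
            break
    excluded = {(i, j) for v, i, j in edges if v < threshold}
    return threshold, excluded
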