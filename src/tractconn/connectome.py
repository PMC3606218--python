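"""Connection-matrix construction from retained streamlines.

Each retained streamline whose two endpoints fall inside labelled
parcellation voxels is assigned to the unordered ROI pair (i, j) and
contributes to three symmetric matrices: the fiber count |B(i,j)|, the
length-corrected connection density M(i,j) = Σ_{f∈B(i,j)} 1/l(f)
(which removes the linear seeding bias toward long fibers), and the
mean FA of the bundle.  Self-connections live on the diagonal: they
count toward subject totals but are never tested regionally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .atlas import Parcellation
from .tracking import Streamline, Tractogram

__all__ = [
    "ConnectionMatrix",
    "assign_endpoints",
    "build_connection_matrix",
    "total_fiber_count",
]


@dataclass
class ConnectionMatrix:
    """Per-subject symmetric edge matrices over the parcellation nodes."""

    subject_id: str
    count: np.ndarray
    density: np.ndarray
    fa_mean: np.ndarray

    def __post_init__(self) -> None:
        for name in ("count", "density", "fa_mean"):
            m = np.asarray(getattr(self, name))
            if m.ndim != 2 or m.shape[0] != m.shape[1]:
                raise ValueError(f"{name} must be square")
            if not np.allclose(m, m.T):
                raise ValueError(f"{name} must be symmetric")
        if (self.count < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def n_nodes(self) -> int:
        return self.count.shape[0]

    def total_fibers(self) -> int:
        """Total retained fibers: upper triangle plus the diagonal."""
        return int(np.triu(self.count).sum())


def total_fiber_count(matrix: ConnectionMatrix) -> int:
    return matrix.total_fibers()


def assign_endpoints(
    streamline: Streamline, parcellation: Parcellation
) -> Optional[tuple[int, int]]:
    """ROI-id pair for a retained streamline's endpoints, or ``None``.

    Each endpoint maps to the label of its containing voxel; background
    (label 0) or out-of-volume endpoints make the fiber unassignable.
    Excluded parcels are assigned normally — exclusion is applied at
    the statistics stage only.
    """
    if parcellation.label_volume is None:
        raise ValueError("parcellation has no label volume")
    labels = parcellation.label_volume
    shape = np.asarray(labels.shape)
    pair = []
    for endpoint in (streamline.points[0], streamline.points[-1]):
        vox = np.floor(np.asarray(endpoint, dtype=float)).astype(int)
        if (vox < 0).any() or (vox >= shape).any():
            return None
        lab = int(labels[tuple(vox)])
        if lab == 0:
            return None
        pair.append(lab)
    return (pair[0], pair[1])


def build_connection_matrix(
    tractogram: Tractogram,
    parcellation: Parcellation,
    subject_id: str = "subject",
    voxel_size: Optional[tuple[float, float, float]] = None,
) -> ConnectionMatrix:
    """Accumulate count, density and mean-FA matrices from a tractogram.

    Only retained streamlines enter; fibers whose endpoints cannot be
    assigned are excluded from all three matrices (their number is kept
    on the result as ``n_unassigned``).  Endpoint voxels are found in
    the label volume's own grid, so streamline mm coordinates are
    converted with the tractogram voxel size.
    """
    n = parcellation.n_nodes
    count = np.zeros((n, n), dtype=np.int64)
    density = np.zeros((n, n))
    fa_sum = np.zeros((n, n))
    n_unassigned = 0
    vs = np.asarray(voxel_size or tractogram.voxel_size, dtype=float)

    for sl in tractogram.retained:
        pair = _assign_in_voxel_space(sl, parcellation, vs)
        if pair is None:
            n_unassigned += 1
            continue
        length = sl.length
        if length <= 0:
            raise ValueError("assigned fiber with non-positive length")
        i = parcellation.index_of(pair[0])
        j = parcellation.index_of(pair[1])
        i, j = min(i, j), max(i, j)
        count[i, j] += 1
        density[i, j] += 1.0 / length
        fa_sum[i, j] += sl.mean_fa if sl.mean_fa is not None else 0.0
        sl.endpoint_rois = pair

    with np.errstate(invalid="ignore"):
        fa_mean = np.where(count > 0, fa_sum / np.maximum(count, 1), 0.0)
    count = count + np.triu(count, 1).T
    density = density + np.triu(density, 1).T
    fa_mean = fa_mean + np.triu(fa_mean, 1).T
    cm = ConnectionMatrix(
        subject_id=subject_id, count=count, density=density, fa_mean=fa_mean
    )
    cm.n_unassigned = n_unassigned
    assert cm.total_fibers() + n_unassigned == len(tractogram.retained)
    return cm


def _assign_in_voxel_space(
    sl: Streamline, parcellation: Parcellation, voxel_size: np.ndarray
) -> Optional[tuple[int, int]]:
    """Assign endpoints after mm -> voxel conversion."""
    if parcellation.label_volume is None:
        raise ValueError("parcellation has no label volume")
    labels = parcellation.label_volume
    shape = np.asarray(labels.shape)
    pair = []
    for endpoint in (sl.points[0], sl.points[-1]):
        vox = np.floor(np.asarray(endpoint, dtype=float) / voxel_size).astype(int)
        if (vox < 0).any() or (vox >= shape).any():
            return None
        lab = int(labels[tuple(vox)])
        if lab == 0:
            return None
        pair.append(lab)
    return (pair[0], pair[1])


def matrix_to_frame(cm: ConnectionMatrix, parcellation: Parcellation, which: str = "count") -> pd.DataFrame:
    """One matrix as a DataFrame with ROI ids as index/columns."""
    ids = parcellation.roi_table["id"].to_list()
    return pd.DataFrame(getattr(cm, which), index=ids, columns=ids)
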