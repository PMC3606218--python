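"""Deterministic streamline tractography on diffusion-tensor volumes.

Streamlines follow the principal eigenvector of the local tensor
(FACT-style: nearest-neighbour orientation lookup, fixed step of half
the smallest voxel dimension).  Four streamlines are initiated at
deterministic sub-voxel offsets in every white-matter voxel and grow in
both directions until they enter the grey-matter mask, leave the
volume, bend by more than the angular threshold between successive
steps, exceed the maximum length, or hit a voxel with no defined
orientation.  A streamline is retained only when both ends terminate in
grey matter and its arc length lies within [min_length, max_length].

There is no randomness anywhere in this module: identical inputs yield
identical tractograms.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np

__all__ = [
    "TensorVolume",
    "TrackingParams",
    "Streamline",
    "Tractogram",
    "fa_of_tensor",
    "streamline_length",
    "track_from_seed",
    "track_streamlines",
]

_EIG_GAP = 1e-9  # below this λ1-λ2 gap the orientation is undefined


@dataclass
class TensorVolume:
    """Voxel grid of symmetric 3x3 diffusion tensors with tissue masks.

    ``tensors`` has shape (nx, ny, nz, 3, 3); ``voxel_size`` is in mm.
    The voxel->mm affine places the centre of voxel (i,j,k) at
    ((i+0.5)sx, (j+0.5)sy, (k+0.5)sz); world coordinates are mm.
    """

    tensors: np.ndarray
    white_mask: np.ndarray
    grey_mask: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.tensors = np.asarray(self.tensors, dtype=float)
        if self.tensors.ndim != 5 or self.tensors.shape[-2:] != (3, 3):
            raise ValueError("tensors must have shape (nx, ny, nz, 3, 3)")
        if self.white_mask.shape != self.shape or self.grey_mask.shape != self.shape:
            raise ValueError("mask shape mismatch")
        if not np.allclose(self.tensors, np.swapaxes(self.tensors, -1, -2), atol=1e-8):
            raise ValueError("tensors must be symmetric")
        self._fields_ready = False

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.tensors.shape[:3]

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.voxel_size
        aff[:3, 3] = 0.5 * np.asarray(self.voxel_size)
        return aff

    # ------------------------------------------------------------------
    # cached per-voxel principal direction and FA fields
    def _prepare_fields(self) -> None:
        if self._fields_ready:
            return
        evals, evecs = np.linalg.eigh(self.tensors)  # ascending eigenvalues
        evals = np.clip(evals, 0.0, None)
        self.principal_dir = evecs[..., :, 2]  # eigenvector of the largest λ
        gap = evals[..., 2] - evals[..., 1]
        norms = np.linalg.norm(self.tensors, axis=(-2, -1))
        self.dir_defined = (gap >= _EIG_GAP) & (norms > 0)
        sq = np.sum(evals**2, axis=-1)
        mean = np.mean(evals, axis=-1, keepdims=True)
        num = np.sum((evals - mean) ** 2, axis=-1)
        with np.errstate(invalid="ignore", divide="ignore"):
            fa = np.sqrt(1.5 * num / sq)
        self.fa_volume = np.where(sq > 0, fa, 0.0)
        self._fields_ready = True

    def voxel_of(self, point_mm: np.ndarray) -> tuple[int, int, int]:
        v = np.floor(np.asarray(point_mm) / np.asarray(self.voxel_size)).astype(int)
        return (int(v[0]), int(v[1]), int(v[2]))

    def in_bounds(self, voxel: tuple[int, int, int]) -> bool:
        return all(0 <= voxel[a] < self.shape[a] for a in range(3))

    def voxel_center(self, voxel: Sequence[int]) -> np.ndarray:
        return (np.asarray(voxel, dtype=float) + 0.5) * np.asarray(self.voxel_size)


@dataclass
class TrackingParams:
    """Streamline growth and retention criteria (lengths in mm)."""

    seeds_per_voxel: int = 4
    max_angle: float = 60.0
    min_length: float = 3.0
    max_length: float = 1000.0
    step_size: Optional[float] = None  # default: half the smallest voxel dim

    def __post_init__(self) -> None:
        if not (0 < self.min_length < self.max_length):
            raise ValueError("require 0 < min_length < max_length")
        if not (0 < self.max_angle <= 90):
            raise ValueError("require 0 < max_angle <= 90")

    def resolve_step(self, voxel_size: Sequence[float]) -> float:
        if self.step_size is not None:
            return float(self.step_size)
        return 0.5 * float(min(voxel_size))


@dataclass
class Streamline:
    """A 3-D polyline in mm coordinates with retention metadata."""

    points: np.ndarray
    retained: bool = False
    endpoint_rois: Optional[tuple[int, int]] = None
    mean_fa: Optional[float] = None

    @property
    def length(self) -> float:
        if len(self.points) < 2:
            return 0.0
        return streamline_length(self.points)


@dataclass
class Tractogram:
    streamlines: list[Streamline] = field(default_factory=list)
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    dimensions: tuple[int, int, int] = (0, 0, 0)

    def __len__(self) -> int:
        return len(self.streamlines)

    def __iter__(self) -> Iterator[Streamline]:
        return iter(self.streamlines)

    @property
    def retained(self) -> list[Streamline]:
        return [s for s in self.streamlines if s.retained]


def fa_of_tensor(tensor: np.ndarray) -> float:
    """Fractional anisotropy of a symmetric 3x3 tensor.

    FA = sqrt(3/2) * ||λ - mean(λ)|| / ||λ|| over the eigenvalues; the
    zero tensor maps to 0 by convention.  Tiny negative eigenvalues from
    numerical noise are clipped.
    """
    t = np.asarray(tensor, dtype=float)
    if t.shape != (3, 3):
        raise ValueError("tensor must be 3x3")
    if not np.allclose(t, t.T, atol=1e-8):
        raise ValueError("tensor must be symmetric")
    evals = np.clip(np.linalg.eigvalsh(t), 0.0, None)
    sq = float(np.sum(evals**2))
    if sq == 0.0:
        return 0.0
    num = float(np.sum((evals - evals.mean()) ** 2))
    return float(np.sqrt(1.5 * num / sq))


def streamline_length(points: np.ndarray) -> float:
    """Arc length (mm) of a polyline: sum of Euclidean segment lengths."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("need at least 2 points")
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def _propagate(
    vol: TensorVolume,
    start: np.ndarray,
    first_dir: np.ndarray,
    step: float,
    params: TrackingParams,
    length_budget: float,
) -> tuple[list[np.ndarray], bool, float]:
    """Grow one half-streamline; return (points beyond start, ended_in_grey, length)."""
    points: list[np.ndarray] = []
    pos = start.copy()
    prev_dir = first_dir / np.linalg.norm(first_dir)
    cos_max = math.cos(math.radians(params.max_angle))
    length = 0.0
    while True:
        vox = vol.voxel_of(pos)
        if not vol.in_bounds(vox):
            return points, False, length
        if vol.grey_mask[vox]:
            return points, True, length  # terminal: reached grey matter
        if not vol.white_mask[vox]:
            return points, False, length  # background
        if not vol.dir_defined[vox]:
            return points, False, length  # isotropic: orientation undefined
        d = vol.principal_dir[vox]
        cos = float(np.dot(d, prev_dir))
        if cos < 0:
            d, cos = -d, -cos  # sign continuity with the previous step
        if points and cos < cos_max:
            return points, False, length  # bend exceeds max_angle
        if length + step > length_budget:
            return points, False, length  # max_length reached
        pos = pos + step * d
        length += step
        points.append(pos.copy())
        prev_dir = d


def track_from_seed(
    vol: TensorVolume, seed_point: Sequence[float], params: TrackingParams | None = None
) -> Streamline:
    """Grow one streamline bidirectionally from a seed point (mm)."""
    params = params or TrackingParams()
    vol._prepare_fields()
    seed = np.asarray(seed_point, dtype=float)
    vox = vol.voxel_of(seed)
    if not vol.in_bounds(vox) or not vol.white_mask[vox]:
        raise ValueError(f"seed {seed} is not inside the white-matter mask")
    step = params.resolve_step(vol.voxel_size)
    if not vol.dir_defined[vox]:
        return Streamline(points=seed[None, :], retained=False)
    d0 = vol.principal_dir[vox]
    fwd, fwd_grey, l_fwd = _propagate(vol, seed, d0, step, params, params.max_length)
    bwd, bwd_grey, _ = _propagate(
        vol, seed, -d0, step, params, params.max_length - l_fwd
    )
    pts = bwd[::-1] + [seed] + fwd
    sl = Streamline(points=np.asarray(pts))
    length = sl.length
    sl.retained = (
        fwd_grey and bwd_grey and params.min_length <= length <= params.max_length
    )
    return sl


# fixed sub-voxel seed offsets (fractions of the voxel), 4 per voxel
_SEED_OFFSETS = np.array(
    [[-0.25, -0.25, 0.0], [-0.25, 0.25, 0.0], [0.25, -0.25, 0.0], [0.25, 0.25, 0.0]]
)


def track_streamlines(
    vol: TensorVolume, params: TrackingParams | None = None
) -> Tractogram:
    """Whole-volume tractography: ``seeds_per_voxel`` seeds per white voxel.

    Seeds sit at fixed sub-voxel offsets, so the output is deterministic.
    Each retained streamline carries its mean FA over traversed voxels.
    """
    params = params or TrackingParams()
    vol._prepare_fields()
    voxels = np.argwhere(vol.white_mask)
    tg = Tractogram(voxel_size=vol.voxel_size, dimensions=vol.shape)
    if len(voxels) == 0:
        warnings.warn("empty white-matter mask: no streamlines initiated")
        return tg
    offsets = _SEED_OFFSETS[: params.seeds_per_voxel]
    vs = np.asarray(vol.voxel_size)
    for vox in voxels:
        center = vol.voxel_center(vox)
        for off in offsets:
            sl = track_from_seed(vol, center + off * vs, params)
            if sl.retained:
                sl.mean_fa = fiber_mean_fa(sl, vol)
            tg.streamlines.append(sl)
    for sl in tg.retained:  # retention contract, asserted on every run
        assert params.min_length <= sl.length <= params.max_length
    return tg


def fiber_mean_fa(streamline: Streamline, vol: TensorVolume) -> float:
    """Mean FA over the distinct voxels traversed by a streamline."""
    vol._prepare_fields()
    pts = np.asarray(streamline.points, dtype=float)
    if len(pts) == 0:
        raise ValueError("empty streamline")
    vox = np.floor(pts / np.asarray(vol.voxel_size)).astype(int)
    vox = vox[np.all((vox >= 0) & (vox < np.array(vol.shape)), axis=1)]
    if len(vox) == 0:
        raise ValueError("streamline does not traverse the volume")
    uniq = np.unique(vox, axis=0)
    return float(np.mean(vol.fa_volume[uniq[:, 0], uniq[:, 1], uniq[:, 2]]))
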