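"""Normalized-FA edge exclusion before group comparison.

Short, near-diagonal connections carry the least reliable fibers and
the lowest FA.  The filter (1) normalizes each control subject's
mean-FA matrix by its own maximum edge value to remove inter-individual
FA scale differences, (2) averages the normalized matrices over the
control group, and (3) walks up the percentiles of the resulting edge
distribution, inspecting edges from the lowest value upward, until it
meets an edge that is *not* situated near the matrix diagonal (i.e. not
a short fiber).  All edges below that stopping edge's value are
excluded from the group comparisons.  The recorded threshold is a
property of the cohort at hand, not a fixed constant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .connectome import ConnectionMatrix

__all__ = [
    "EdgeMask",
    "normalize_fa_matrix",
    "group_mean_fa_matrix",
    "derive_edge_mask",
    "apply_mask",
]


@dataclass
class EdgeMask:
    """Boolean keep-matrix with the stopping threshold that produced it."""

    keep: np.ndarray
    threshold: float
    stop_quantile: float

    def __post_init__(self) -> None:
        if not np.array_equal(self.keep, self.keep.T):
            raise ValueError("keep mask must be symmetric")

    @property
    def n_excluded(self) -> int:
        return int((~self.keep[np.triu_indices(self.keep.shape[0])]).sum())


def normalize_fa_matrix(fa_mean: np.ndarray, mode: str = "max") -> np.ndarray:
    """Scale a subject's mean-FA matrix into (0, 1].

    ``mode='max'`` divides every nonzero edge by the subject's maximum
    edge value (default); ``mode='mean'`` divides by the mean of the
    nonzero edges.  Zero (absent) edges stay zero.
    """
    m = np.asarray(fa_mean, dtype=float)
    nz = m > 0
    if not nz.any():
        raise ValueError("all-zero FA matrix cannot be normalized")
    if mode == "max":
        denom = m[nz].max()
    elif mode == "mean":
        denom = m[nz].mean()
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    out = np.zeros_like(m)
    out[nz] = m[nz] / denom
    return out


def group_mean_fa_matrix(
    normalized: Sequence[np.ndarray], zero_fill: bool = False
) -> np.ndarray:
    """Per-edge mean of normalized control matrices.

    By default an edge's mean is taken over the subjects in which the
    edge is present (nonzero); ``zero_fill=True`` instead averages over
    all subjects, counting absences as zeros.  Edges absent in every
    subject stay zero (empty).
    """
    mats = [np.asarray(m, dtype=float) for m in normalized]
    if len(mats) < 1:
        raise ValueError("empty control set")
    stack = np.stack(mats)
    if zero_fill:
        return stack.mean(axis=0)
    present = stack > 0
    n_present = present.sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.where(n_present > 0, stack.sum(axis=0) / np.maximum(n_present, 1), 0.0)
    return mean


def _percentile_rank(sorted_values: np.ndarray, k: int) -> float:
    """Rank (in percent) such that np.percentile(values, rank) == values[k]."""
    n = len(sorted_values)
    if n == 1:
        return 0.0
    return 100.0 * k / (n - 1)


def derive_edge_mask(mean_matrix: np.ndarray, diagonal_band: int = 1) -> EdgeMask:
    """Quantile-stepping exclusion of low-FA short-fiber edges.

    Walk the percentiles q = 1, 2, 3, ... of the distribution of
    present-edge values; at each step inspect every not-yet-inspected
    edge whose value is <= the q-th percentile value, in ascending
    order.  Stop at the first inspected edge that is *not* within
    ``diagonal_band`` of the main diagonal (|i - j| > band); all edges
    with value strictly below that edge's value are excluded.  The
    recorded threshold is the stopping edge's value and ``stop_quantile``
    its (interpolation-consistent) percentile rank, so that
    ``np.percentile(values, stop_quantile) == threshold``.

    With fewer than 100 present edges the percentile values come from
    order statistics with linear interpolation (numpy's default), so
    small matrices exercise the identical procedure.
    """
    m = np.asarray(mean_matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("mean matrix must be square")
    if diagonal_band < 0:
        raise ValueError("diagonal_band must be >= 0")
    n = m.shape[0]
    iu = np.triu_indices(n)
    present = m[iu] > 0
    if not present.any():
        raise ValueError("mean matrix has no present edges")
    vals = m[iu][present]
    rows = iu[0][present]
    cols = iu[1][present]
    order = np.argsort(vals, kind="stable")
    vals_sorted = vals[order]
    offdiag = np.abs(rows - cols)[order] > diagonal_band

    stop_idx = None
    inspected = 0
    for q in range(1, 101):
        vq = np.percentile(vals_sorted, min(q, 100))
        while inspected < len(vals_sorted) and vals_sorted[inspected] <= vq:
            if offdiag[inspected]:
                stop_idx = inspected
                break
            inspected += 1
        if stop_idx is not None:
            break
    if stop_idx is None:
        # every inspected edge sat in the band; the highest edge stops the scan
        stop_idx = len(vals_sorted) - 1
    threshold = float(vals_sorted[stop_idx])
    stop_quantile = _percentile_rank(vals_sorted, stop_idx)

    keep = np.ones((n, n), dtype=bool)
    excl = vals < threshold
    keep[rows[excl], cols[excl]] = False
    keep[cols[excl], rows[excl]] = False
    return EdgeMask(keep=keep, threshold=threshold, stop_quantile=stop_quantile)


def apply_mask(matrix: np.ndarray, mask: EdgeMask) -> np.ndarray:
    """Set excluded cells to NaN (missing for the statistics stage).

    Subject totals for the global comparison are computed from the
    unmasked matrix; this masking affects the per-connection tests only.
    """
    m = np.asarray(matrix, dtype=float)
    if m.shape != mask.keep.shape:
        raise ValueError("matrix/mask dimension mismatch")
    out = m.copy()
    out[~mask.keep] = np.nan
    return out


def control_edge_mask(
    control_matrices: Sequence[ConnectionMatrix],
    diagonal_band: int = 1,
    normalization: str = "max",
    zero_fill: bool = False,
) -> EdgeMask:
    """Full three-step procedure from control subjects' FA matrices."""
    if len(control_matrices) < 2:
        raise ValueError("need at least 2 control subjects")
    normalized = [normalize_fa_matrix(cm.fa_mean, mode=normalization) for cm in control_matrices]
    mean = group_mean_fa_matrix(normalized, zero_fill=zero_fill)
    return derive_edge_mask(mean, diagonal_band=diagonal_band)
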