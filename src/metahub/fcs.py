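"""Voxelwise functional connectivity strength (FCS).

FCS is a weighted degree centrality: for each voxel, the sum of Pearson
correlations to all other voxels, keeping only positive correlations at or
above ``r_threshold`` between voxels farther apart than ``min_distance_mm``
(the short-distance exclusion removes shared-signal bias between
neighbouring voxels). The raw map is then z-normalized across voxels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .grid import VoxelGrid, VoxelMap

logger = logging.getLogger("metahub")


class DegenerateMapError(ValueError):
    """Raised when a map is constant and cannot be normalized."""


@dataclass(frozen=True)
class FcsParams:
    """Connection-filter settings.

    ``r_threshold`` zeroes correlations strictly below it (r exactly at the
    threshold is kept); ``min_distance_mm`` zeroes pairs at center distance
    <= the cutoff; negative correlations are always excluded when
    ``exclude_negative`` is on.
    """

    r_threshold: float = 0.1
    min_distance_mm: float = 20.0
    exclude_negative: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.r_threshold < 1):
            raise ValueError("r_threshold must be in [0, 1)")
        if self.min_distance_mm < 0:
            raise ValueError("min_distance_mm must be >= 0")


def _correlation_from_timeseries(ts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Full correlation matrix plus a zero-variance voxel flag."""
    ts = np.asarray(ts, dtype=float)
    sd = ts.std(axis=1)
    bad = sd == 0
    if bad.any():
        logger.warning("%d zero-variance voxels; their connections set to 0", bad.sum())
    safe = ts.copy()
    safe[bad] = 0.0
    centered = safe - safe.mean(axis=1, keepdims=True)
    denom = np.sqrt((centered**2).sum(axis=1))
    denom[denom == 0] = 1.0
    corr = (centered / denom[:, None]) @ (centered / denom[:, None]).T
    corr[bad, :] = 0.0
    corr[:, bad] = 0.0
    return corr, bad


def compute_fcs(
    data: np.ndarray,
    grid: VoxelGrid,
    params: FcsParams = FcsParams(),
    block_size: int = 2048,
) -> VoxelMap:
    """Raw FCS from a (n_gray, n_time) series array or an (n_gray, n_gray)
    correlation matrix.

    FCS(v) = sum over u != v of r(v, u) restricted to r >= r_threshold,
    r > 0 (when negatives are excluded) and distance(v, u) > min_distance_mm.
    Evaluation is blocked over voxel rows so the full matrix never has to be
    materialized for time-series input.
    """
    data = np.asarray(data, dtype=float)
    n = grid.n_gray
    if data.ndim != 2:
        raise ValueError("input must be 2-D (series or correlation matrix)")
    if data.shape[0] != n:
        raise ValueError(f"first dimension must be the {n} gray voxels")
    if n < 2:
        raise ValueError("need at least 2 voxels")
    coords = grid.coords_mm()

    is_corr = data.shape == (n, n) and np.allclose(data, data.T) and np.allclose(
        np.diag(data), 1.0
    )
    if is_corr:
        if not np.isfinite(data).all():
            raise ValueError("correlation matrix entries must be finite")
        corr_rows = lambda sl: data[sl]  # noqa: E731
    else:
        sd = data.std(axis=1)
        bad = sd == 0
        if bad.any():
            logger.warning(
                "%d zero-variance voxels; their connections set to 0", int(bad.sum())
            )
        safe = data - data.mean(axis=1, keepdims=True)
        norm = np.sqrt((safe**2).sum(axis=1))
        norm[norm == 0] = 1.0
        unit = safe / norm[:, None]
        unit[bad] = 0.0

        def corr_rows(sl):
            return unit[sl] @ unit.T

    fcs = np.zeros(n)
    for start in range(0, n, block_size):
        sl = slice(start, min(start + block_size, n))
        rows = np.array(corr_rows(sl), dtype=float, copy=True)
        # distance exclusion (also kills the self-correlation diagonal)
        d = np.linalg.norm(coords[sl][:, None, :] - coords[None, :, :], axis=2)
        rows[d <= params.min_distance_mm] = 0.0
        rows[rows < params.r_threshold] = 0.0
        if params.exclude_negative:
            rows[rows < 0] = 0.0
        fcs[sl] = rows.sum(axis=1)
    return VoxelMap(grid, fcs)


def normalize_fcs(raw: VoxelMap) -> VoxelMap:
    """Z-normalize an FCS map across gray-mask voxels (population SD)."""
    v = raw.values
    if v.size < 2:
        raise ValueError("need at least 2 voxels to normalize")
    sd = v.std()  # population convention (divide by n)
    if sd == 0:
        raise DegenerateMapError("constant FCS map cannot be normalized")
    return raw.copy_with((v - v.mean()) / sd)
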