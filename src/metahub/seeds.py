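"""Seed-to-whole-brain connectivity profiles and their clustering.

A hub seed is a 6-mm-radius sphere around a peak; its mean time series is
correlated with every gray voxel and Fisher-z transformed. The per-subject
z maps go through the same cohort GLM → random-effects meta-analysis →
max-Z permutation thresholding chain as the FCS maps. The significant map
is summarized as a network-coverage profile (percentage of each network's
voxels connected with the hub), and profiles across hubs are grouped by
agglomerative hierarchical clustering (single linkage, Euclidean distance).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from .glm import fit_cohort_glm
from .grid import VoxelGrid, VoxelMap
from .inference import identify_hubs

logger = logging.getLogger("metahub")

_FISHER_CAP = 1.0 - 1e-7


class InvalidSeedError(ValueError):
    pass


@dataclass(frozen=True)
class SeedSpec:
    """Spherical seed: center (MNI mm) and radius (default 6 mm)."""

    center: tuple[float, float, float]
    radius_mm: float = 6.0


def seed_sphere_voxels(grid: VoxelGrid, seed: SeedSpec) -> np.ndarray:
    """Gray-voxel indices whose centers lie within the seed sphere (inclusive)."""
    d = np.linalg.norm(grid.coords_mm() - np.asarray(seed.center), axis=1)
    idx = np.flatnonzero(d <= seed.radius_mm)
    if len(idx) == 0:
        raise InvalidSeedError(f"seed sphere at {seed.center} contains no gray voxel")
    return idx


def seed_fisher_z(timeseries: np.ndarray, seed: SeedSpec, grid: VoxelGrid) -> VoxelMap:
    """Fisher-z map of correlations between the seed-mean series and every voxel.

    |r| is capped at 1 - 1e-7 before arctanh so a voxel inside the seed
    cannot produce an infinite z.
    """
    ts = np.asarray(timeseries, dtype=float)
    if ts.shape[0] != grid.n_gray:
        raise ValueError("timeseries must be (n_gray, n_time)")
    idx = seed_sphere_voxels(grid, seed)
    seed_ts = ts[idx].mean(axis=0)
    if seed_ts.std() == 0:
        raise InvalidSeedError("seed mean series has zero variance")
    sc = seed_ts - seed_ts.mean()
    vc = ts - ts.mean(axis=1, keepdims=True)
    denom = np.sqrt((vc**2).sum(axis=1)) * np.sqrt((sc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (vc @ sc) / denom
    r[~np.isfinite(r)] = 0.0
    r = np.clip(r, -_FISHER_CAP, _FISHER_CAP)
    return VoxelMap(grid, np.arctanh(r))


def seed_meta(
    z_maps_by_cohort: list[np.ndarray],
    ages_by_cohort: list[np.ndarray],
    sexes_by_cohort: list[np.ndarray],
    grid: VoxelGrid,
    n_permutations: int = 10_000,
    alpha: float = 0.001,
    min_cluster_mm3: float = 200.0,
    seed: int = 0,
):
    """Meta-analytic significant-connectivity map from per-subject Fisher-z maps.

    Chains the cohort GLM, the random-effects meta-analysis and the
    permutation/cluster thresholding on the z maps; returns
    (HubResult, MetaResult) where the hub mask is the significant map.
    """
    summaries = [
        fit_cohort_glm(maps, ages, sexes, cohort_id=f"cohort{i:03d}")[0]
        for i, (maps, ages, sexes) in enumerate(
            zip(z_maps_by_cohort, ages_by_cohort, sexes_by_cohort)
        )
    ]
    return identify_hubs(
        summaries,
        grid,
        n_permutations=n_permutations,
        alpha=alpha,
        min_cluster_mm3=min_cluster_mm3,
        seed=seed,
    )


def connectivity_profile(significant_mask: np.ndarray, grid: VoxelGrid) -> np.ndarray:
    """Network-coverage profile: % of each network's gray voxels in the mask."""
    labels = grid.labels_flat()
    n_net = grid.n_networks
    if n_net < 2:
        raise ValueError("grid must define at least 2 networks")
    significant_mask = np.asarray(significant_mask, dtype=bool)
    profile = np.empty(n_net)
    for net in range(1, n_net + 1):
        in_net = labels == net
        if in_net.sum() == 0:
            logger.warning("network %d is empty; coverage set to NaN", net)
            profile[net - 1] = np.nan
        else:
            profile[net - 1] = 100.0 * (significant_mask & in_net).sum() / in_net.sum()
    return profile


def cluster_profiles(
    profiles: np.ndarray,
    n_clusters: int | None = None,
    method: str = "single",
    metric: str = "euclidean",
) -> tuple[np.ndarray, np.ndarray | None]:
    """Agglomerative clustering of hub connectivity profiles.

    ``profiles`` is (n_networks, n_hubs); columns are clustered. Returns the
    linkage matrix and, when ``n_clusters`` is given, a flat cluster
    assignment per hub.
    """
    profiles = np.asarray(profiles, dtype=float)
    if profiles.ndim != 2 or profiles.shape[1] < 2:
        raise ValueError("need at least 2 hub profiles to cluster")
    tree = linkage(profiles.T, method=method, metric=metric)
    assignment = None
    if n_clusters is not None:
        assignment = fcluster(tree, t=n_clusters, criterion="maxclust")
    return tree, assignment
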