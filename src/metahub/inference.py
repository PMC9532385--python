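"""Hub inference: max-statistic permutation FWER, thresholding, peaks.

The family-wise error rate over voxels is controlled by a max-Z
permutation test: each iteration randomizes the spatial correspondence
among cohorts' mean maps — an independent voxel permutation per cohort,
applied jointly to that cohort's mean and variance maps so their pairing
is preserved — reruns the random-effects meta-analysis, and records the
maximum Z over voxels. Voxel p-values against that null distribution are
then thresholded (p < alpha) with a cluster-extent rule (> min mm^3), and
local peaks at least ``min_separation_mm`` apart are extracted per cluster.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .glm import CohortSummary
from .grid import VoxelGrid, VoxelMap
from .meta import InsufficientCohortsError, effect_size, meta_z, random_effects_meta


@dataclass
class PermutationNull:
    """Null distribution of the map-wide maximum Z under spatial permutation."""

    max_z_values: np.ndarray
    n_iterations: int
    seed: int

    def __post_init__(self) -> None:
        self.max_z_values = np.asarray(self.max_z_values, dtype=float)
        if len(self.max_z_values) != self.n_iterations:
            raise ValueError("one maximum per iteration")


@dataclass
class HubResult:
    p_map: VoxelMap
    hub_mask: np.ndarray  # bool per gray voxel
    cluster_labels: np.ndarray  # int per gray voxel, 0 = background
    peaks: pd.DataFrame


def permutation_null(
    summaries: list[CohortSummary],
    n_iterations: int = 10_000,
    seed: int = 0,
) -> PermutationNull:
    """Build the max-Z null by independently permuting each cohort's voxels."""
    if len(summaries) < 2:
        raise InsufficientCohortsError("need at least 2 cohorts")
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    means = np.stack([s.mean_map for s in summaries])
    variances = np.stack([s.variance_map for s in summaries])
    n_subjects = np.array([s.n_subjects for s in summaries], dtype=float)
    k, n_vox = means.shape
    rng = np.random.default_rng(seed)
    maxima = np.empty(n_iterations)
    for it in range(n_iterations):
        perm_means = np.empty_like(means)
        perm_vars = np.empty_like(variances)
        for c in range(k):
            p = rng.permutation(n_vox)
            perm_means[c] = means[c, p]
            perm_vars[c] = variances[c, p]
        z = meta_z(perm_means, perm_vars, n_subjects)
        maxima[it] = np.nanmax(z)
    return PermutationNull(max_z_values=maxima, n_iterations=n_iterations, seed=seed)


def assign_p(z_map: VoxelMap, null: PermutationNull) -> VoxelMap:
    """One-sided p(v) = (1 + #{null >= Z(v)}) / (n + 1), never zero."""
    if null.n_iterations < 1:
        raise ValueError("empty null distribution")
    null_sorted = np.sort(null.max_z_values)
    z = z_map.values
    # count of null values >= z via searchsorted on the sorted null
    n_ge = null.n_iterations - np.searchsorted(null_sorted, z, side="left")
    p = (1.0 + n_ge) / (null.n_iterations + 1.0)
    p[~np.isfinite(z)] = np.nan
    return z_map.copy_with(p)


_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def threshold_hubs(
    p_map: VoxelMap,
    z_map: VoxelMap,
    alpha: float = 0.001,
    min_cluster_mm3: float = 200.0,
    grid: VoxelGrid | None = None,
    connectivity: np.ndarray = _STRUCT_26,
) -> HubResult:
    """Threshold at p < alpha and keep 26-connected clusters > min_cluster_mm3."""
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if min_cluster_mm3 < 0:
        raise ValueError("min_cluster_mm3 must be >= 0")
    grid = grid or p_map.grid
    supra_flat = p_map.values < alpha
    supra_vol = grid.embed(supra_flat.astype(float)) > 0.5
    labeled, n_comp = ndimage.label(supra_vol, structure=connectivity)
    vox_mm3 = grid.voxel_volume_mm3
    keep = np.zeros(n_comp + 1, dtype=bool)
    if n_comp:
        sizes = np.bincount(labeled.ravel(), minlength=n_comp + 1)
        keep[1:] = sizes[1:] * vox_mm3 > min_cluster_mm3
    kept_vol = np.where(keep[labeled], labeled, 0)
    # relabel kept components 1..m in order of first appearance
    old = np.unique(kept_vol)
    old = old[old > 0]
    relabel = np.zeros(n_comp + 1, dtype=int)
    relabel[old] = np.arange(1, len(old) + 1)
    kept_vol = relabel[kept_vol]

    cluster_flat = grid.extract(kept_vol.astype(float)).astype(int)
    hub_mask = cluster_flat > 0
    return HubResult(
        p_map=p_map,
        hub_mask=hub_mask,
        cluster_labels=cluster_flat,
        peaks=pd.DataFrame(),
    )


def _local_maxima(
    grid: VoxelGrid, z_flat: np.ndarray, cluster_flat: np.ndarray
) -> np.ndarray:
    """Flat gray-voxel indices of strict 26-neighborhood local maxima inside
    clusters (out-of-cluster neighbors are ignored)."""
    z_vol = grid.embed(z_flat, fill=-np.inf)
    lab_vol = grid.embed(cluster_flat.astype(float)).astype(int)
    z_in = np.where(lab_vol > 0, z_vol, -np.inf)
    nx, ny, nz = grid.dims
    is_max = lab_vol > 0
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if dx == dy == dz == 0:
                    continue
                shifted = np.full_like(z_in, -np.inf)
                xs = slice(max(dx, 0), nx + min(dx, 0))
                ys = slice(max(dy, 0), ny + min(dy, 0))
                zs = slice(max(dz, 0), nz + min(dz, 0))
                xd = slice(max(-dx, 0), nx + min(-dx, 0))
                yd = slice(max(-dy, 0), ny + min(-dy, 0))
                zd = slice(max(-dz, 0), nz + min(-dz, 0))
                shifted[xd, yd, zd] = z_in[xs, ys, zs]
                is_max &= z_in > shifted
    max_flat = grid.extract(is_max.astype(float)) > 0.5
    return np.flatnonzero(max_flat & (cluster_flat > 0))


def extract_peaks(
    z_map: VoxelMap,
    hubs: HubResult,
    min_separation_mm: float = 15.0,
    meta=None,
) -> pd.DataFrame:
    """Per-cluster greedy peak extraction.

    Local maxima are sorted by Z descending (ties broken by lowest voxel
    index) and retained greedily when at least ``min_separation_mm`` from
    every already-retained peak of the same cluster. When a
    :class:`~metahub.meta.MetaResult` is supplied, each peak row carries d,
    M* and SE; rows are sorted by d (equivalently Z) descending.
    """
    if min_separation_mm < 0:
        raise ValueError("min_separation_mm must be >= 0")
    grid = z_map.grid
    cluster_flat = hubs.cluster_labels
    cols = ["x", "y", "z", "Z", "d", "m_star", "se", "cluster", "voxel_index"]
    if not (cluster_flat > 0).any():
        return pd.DataFrame(columns=cols)
    cand = _local_maxima(grid, z_map.values, cluster_flat)
    coords = grid.coords_mm()
    rows = []
    for cl in np.unique(cluster_flat[cluster_flat > 0]):
        in_cl = cand[cluster_flat[cand] == cl]
        if len(in_cl) == 0:
            # flat plateau: no strict local maximum exists, so fall back to
            # the cluster's maximum-Z voxel (lowest index among exact ties)
            members = np.flatnonzero(cluster_flat == cl)
            in_cl = members[[int(np.argmax(z_map.values[members]))]]
        order = sorted(in_cl, key=lambda v: (-z_map.values[v], v))
        kept: list[int] = []
        for v in order:
            if all(
                np.linalg.norm(coords[v] - coords[u]) >= min_separation_mm
                for u in kept
            ):
                kept.append(v)
        for v in kept:
            zv = z_map.values[v]
            rows.append(
                {
                    "x": coords[v, 0],
                    "y": coords[v, 1],
                    "z": coords[v, 2],
                    "Z": zv,
                    "d": meta.d[v] if meta is not None else np.nan,
                    "m_star": meta.m_star[v] if meta is not None else np.nan,
                    "se": meta.se[v] if meta is not None else np.nan,
                    "cluster": int(cl),
                    "voxel_index": int(v),
                }
            )
    table = pd.DataFrame(rows, columns=cols)
    sort_key = "d" if meta is not None else "Z"
    return table.sort_values(sort_key, ascending=False, kind="stable").reset_index(
        drop=True
    )


def identify_hubs(
    summaries: list[CohortSummary],
    grid: VoxelGrid,
    n_permutations: int = 10_000,
    alpha: float = 0.001,
    min_cluster_mm3: float = 200.0,
    peak_separation_mm: float = 15.0,
    seed: int = 0,
) -> tuple[HubResult, "object"]:
    """Full hub-identification pipeline on cohort summaries.

    Runs the random-effects meta-analysis, the max-Z permutation test, the
    p/cluster thresholding and the peak extraction; returns the hub result
    (with the peak table filled) and the meta result.
    """
    meta = effect_size(random_effects_meta(summaries))
    z_map = VoxelMap(grid, meta.z)
    null = permutation_null(summaries, n_iterations=n_permutations, seed=seed)
    p_map = assign_p(z_map, null)
    hubs = threshold_hubs(p_map, z_map, alpha=alpha, min_cluster_mm3=min_cluster_mm3)
    hubs.peaks = extract_peaks(z_map, hubs, min_separation_mm=peak_separation_mm, meta=meta)
    return hubs, meta
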