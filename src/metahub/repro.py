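"""Reproducibility analyses: leave-one-cohort-out, hub occurrence, subsampling.

These quantify whether an identified hub topography is dominated by single
cohorts (leave-one-cohort-out Dice and peak displacement), whether it is
shared across units (hub occurrence probability, the fraction of subjects
or cohorts whose top-N connectivity-strength voxels contain a given voxel),
and how many units are needed for a stable map (subsampling Dice curves).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .glm import CohortSummary
from .grid import GridIncompatibilityError, VoxelGrid
from .inference import identify_hubs

logger = logging.getLogger("metahub")


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice's coefficient 2|A∩B| / (|A|+|B|); 1.0 when both masks are empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise GridIncompatibilityError("masks must share the grid")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


@dataclass
class ReproReport:
    loco_dice: dict[str, float] = field(default_factory=dict)
    peak_displacements: pd.DataFrame | None = None
    hop_subjects: np.ndarray | None = None
    hop_cohorts: np.ndarray | None = None
    subsample_curves: pd.DataFrame | None = None


def leave_one_cohort_out(
    summaries: list[CohortSummary],
    grid: VoxelGrid,
    n_permutations: int = 1000,
    alpha: float = 0.001,
    min_cluster_mm3: float = 200.0,
    peak_separation_mm: float = 15.0,
    seed: int = 0,
) -> ReproReport:
    """Rerun the hub identification with each cohort left out in turn.

    For every left-out cohort the report records the Dice of the reduced
    hub mask against the all-cohort mask and, for each all-cohort peak, the
    displacement (mm) to the nearest peak of the reduced analysis.
    """
    if len(summaries) < 3:
        raise ValueError("leave-one-out needs at least 3 cohorts")
    full_hubs, _ = identify_hubs(
        summaries,
        grid,
        n_permutations=n_permutations,
        alpha=alpha,
        min_cluster_mm3=min_cluster_mm3,
        peak_separation_mm=peak_separation_mm,
        seed=seed,
    )
    full_peaks = full_hubs.peaks[["x", "y", "z"]].to_numpy()
    report = ReproReport()
    disp_rows = []
    for i, left_out in enumerate(summaries):
        reduced = summaries[:i] + summaries[i + 1 :]
        hubs_i, _ = identify_hubs(
            reduced,
            grid,
            n_permutations=n_permutations,
            alpha=alpha,
            min_cluster_mm3=min_cluster_mm3,
            peak_separation_mm=peak_separation_mm,
            seed=seed,
        )
        report.loco_dice[left_out.cohort_id] = dice(full_hubs.hub_mask, hubs_i.hub_mask)
        red_peaks = hubs_i.peaks[["x", "y", "z"]].to_numpy()
        for p_idx, p in enumerate(full_peaks):
            if len(red_peaks):
                d = float(np.min(np.linalg.norm(red_peaks - p, axis=1)))
            else:
                d = np.nan
            disp_rows.append(
                {"left_out": left_out.cohort_id, "peak": p_idx, "displacement_mm": d}
            )
    report.peak_displacements = pd.DataFrame(disp_rows)
    return report


def _top_n_mask(values: np.ndarray, n_top: int) -> np.ndarray:
    """Boolean top-N mask; boundary ties broken by lowest voxel index."""
    order = np.lexsort((np.arange(len(values)), -values))
    mask = np.zeros(len(values), dtype=bool)
    mask[order[:n_top]] = True
    return mask


def hub_occurrence(maps: np.ndarray, n_top: int) -> np.ndarray:
    """Hub occurrence probability: fraction of units (rows) whose top-N set
    contains each voxel."""
    maps = np.asarray(maps, dtype=float)
    n_units, n_vox = maps.shape
    if not (1 <= n_top <= n_vox):
        raise ValueError("n_top must be within [1, voxel count]")
    counts = np.zeros(n_vox)
    for row in maps:
        if n_top < n_vox:
            part = np.partition(row, [n_vox - n_top - 1, n_vox - n_top])
            if part[n_vox - n_top - 1] == part[n_vox - n_top]:
                logger.warning("tie at the top-N boundary broken by voxel index")
        counts += _top_n_mask(row, n_top)
    return counts / n_units


def subsample_stability(
    maps: np.ndarray,
    reference_mask: np.ndarray,
    sizes: list[int],
    n_selections: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Dice of the subset top-N occurrence mask against a reference mask.

    For each subset size, draws ``n_selections`` random unit subsets
    (without replacement within a draw), computes the hub-occurrence map of
    the subset, takes its top-N voxels (N = reference mask size) and
    records the Dice against the reference; returns mean and SD per size.
    """
    maps = np.asarray(maps, dtype=float)
    reference_mask = np.asarray(reference_mask, dtype=bool)
    n_units = maps.shape[0]
    n_ref = int(reference_mask.sum())
    rng = np.random.default_rng(seed)
    rows = []
    for size in sizes:
        size = int(size)
        if size > n_units or size < 1:
            raise ValueError(f"subset size {size} out of range [1, {n_units}]")
        n_draws = 1 if size == n_units else n_selections
        dices = np.empty(n_draws)
        for s in range(n_draws):
            sel = rng.choice(n_units, size=size, replace=False)
            hop = hub_occurrence(maps[sel], n_ref)
            dices[s] = dice(_top_n_mask(hop, n_ref), reference_mask)
        rows.append(
            {"size": size, "mean_dice": dices.mean(), "sd_dice": dices.std(ddof=0)}
        )
    return pd.DataFrame(rows)
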