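"""Synthetic multi-cohort data with the statistical structure the pipeline assumes.

The generator emulates, at desk scale, the inputs of a multi-cohort
resting-state connectome-hub study:

* per-subject normalized connectivity-strength (FCS) maps that follow the
  per-cohort linear model ``map = mu + u_c + beta_age*(age - mean age) +
  beta_sex*sex + noise`` with a between-cohort random effect
  ``u_c ~ N(0, tau^2)`` per voxel,
* small voxel-by-time rsfMRI-like series with a planted community of
  correlated voxels (high-degree "hub" voxels),
* expression matrices in which a subset of spatially autocorrelated genes
  is shifted in hub samples.

Ages are drawn uniformly on [18, 36] years (a healthy-young-adult
inclusion window) and sexes are Bernoulli(0.5), coded +/-0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import VoxelGrid

AGE_RANGE = (18.0, 36.0)


@dataclass
class GroundTruth:
    """Generative ground truth for a synthetic multi-cohort study.

    ``true_mean_map`` is the per-voxel true normalized FCS (z-scale),
    ``tau2`` the between-cohort variance, ``sigma_within`` the within-cohort
    subject SD, and ``hub_mask_true`` the planted-hub indicator.
    """

    true_mean_map: np.ndarray
    tau2: float
    sigma_within: float
    beta_age: float
    beta_sex: float
    hub_mask_true: np.ndarray
    seed: int = 0

    def __post_init__(self) -> None:
        self.true_mean_map = np.asarray(self.true_mean_map, dtype=float)
        self.hub_mask_true = np.asarray(self.hub_mask_true, dtype=bool)
        if self.tau2 < 0:
            raise ValueError("tau2 must be >= 0")
        if self.sigma_within <= 0:
            raise ValueError("sigma_within must be > 0")
        if self.hub_mask_true.shape != self.true_mean_map.shape:
            raise ValueError("hub mask and mean map must share voxel count")


@dataclass
class SyntheticCohort:
    """One simulated cohort: subject maps plus covariates."""

    cohort_id: str
    subject_maps: np.ndarray  # (n_subjects, n_gray)
    ages: np.ndarray
    sexes: np.ndarray  # +/-0.5 codes
    n_subjects: int = field(init=False)

    def __post_init__(self) -> None:
        self.subject_maps = np.asarray(self.subject_maps, dtype=float)
        self.ages = np.asarray(self.ages, dtype=float)
        self.sexes = np.asarray(self.sexes, dtype=float)
        self.n_subjects = int(self.subject_maps.shape[0])
        if self.n_subjects < 2:
            raise ValueError("a cohort needs at least 2 subjects")
        if not (len(self.ages) == len(self.sexes) == self.n_subjects):
            raise ValueError("one age/sex per subject map")


def make_ground_truth(
    grid: VoxelGrid,
    hub_centers: list[tuple[float, float, float]] | None = None,
    hub_radius_mm: float = 6.0,
    hub_effect: float = 1.0,
    tau2: float = 0.04,
    sigma_within: float = 1.0,
    beta_age: float = 0.0,
    beta_sex: float = 0.0,
    seed: int = 0,
) -> GroundTruth:
    """Plant contiguous spherical hub blobs on a grid.

    The true mean map is ``hub_effect`` inside the spheres and 0 elsewhere,
    so hub voxels exceed the global mean as the hub definition requires.
    Spheres keep the planted hubs contiguous, which exercises
    cluster-extent thresholding downstream.
    """
    coords = grid.coords_mm()
    mean_map = np.zeros(grid.n_gray)
    hub_mask = np.zeros(grid.n_gray, dtype=bool)
    if hub_centers is None:
        # one blob at the grid center by default
        hub_centers = [tuple(coords.mean(axis=0))]
    for c in hub_centers:
        d = np.linalg.norm(coords - np.asarray(c, dtype=float), axis=1)
        hub_mask |= d <= hub_radius_mm
    mean_map[hub_mask] = hub_effect
    return GroundTruth(
        true_mean_map=mean_map,
        tau2=tau2,
        sigma_within=sigma_within,
        beta_age=beta_age,
        beta_sex=beta_sex,
        hub_mask_true=hub_mask,
        seed=seed,
    )


def simulate_cohort_maps(
    grid: VoxelGrid,
    truth: GroundTruth,
    cohort_sizes: list[int],
    seed: int = 0,
) -> list[SyntheticCohort]:
    """Simulate per-subject maps for a list of cohorts.

    Each cohort ``c`` draws a voxelwise random effect ``u_c ~ N(0, tau2)``;
    each subject map is ``true_mean + u_c + beta_age*(age - cohort mean age)
    + beta_sex*sex + eps`` with ``eps ~ N(0, sigma_within^2)`` i.i.d. over
    voxels and subjects.
    """
    if any(int(n) < 2 for n in cohort_sizes):
        raise ValueError("every cohort size must be >= 2")
    n_gray = grid.n_gray
    if truth.true_mean_map.shape != (n_gray,):
        raise ValueError("ground truth does not match grid voxel count")
    rng = np.random.default_rng(seed)
    cohorts = []
    for c, n_sub in enumerate(cohort_sizes):
        n_sub = int(n_sub)
        u_c = rng.normal(0.0, np.sqrt(truth.tau2), size=n_gray)
        ages = rng.uniform(*AGE_RANGE, size=n_sub)
        sexes = rng.integers(0, 2, size=n_sub) - 0.5
        eps = rng.normal(0.0, truth.sigma_within, size=(n_sub, n_gray))
        age_dev = ages - ages.mean()
        maps = (
            truth.true_mean_map[None, :]
            + u_c[None, :]
            + truth.beta_age * age_dev[:, None]
            + truth.beta_sex * sexes[:, None]
            + eps
        )
        cohorts.append(
            SyntheticCohort(
                cohort_id=f"cohort{c:03d}", subject_maps=maps, ages=ages, sexes=sexes
            )
        )
    return cohorts


def block_correlation_matrix(
    n_voxels: int, blocks: list[tuple[list[int], float]]
) -> np.ndarray:
    """Build a population correlation matrix with within-block correlation r.

    ``blocks`` is a list of (voxel index list, r) pairs; voxels outside any
    block are mutually independent.
    """
    corr = np.eye(n_voxels)
    for idx, r in blocks:
        idx = np.asarray(idx, dtype=int)
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                corr[idx[a], idx[b]] = r
                corr[idx[b], idx[a]] = r
    return corr


def simulate_timeseries_cohort(
    grid: VoxelGrid,
    community_spec: np.ndarray | list[tuple[list[int], float]],
    n_timepoints: int = 200,
    n_subjects: int = 1,
    seed: int = 0,
) -> list[np.ndarray]:
    """Simulate per-subject (n_gray, n_timepoints) Gaussian series.

    The population correlation matrix is either given directly or built
    from a block description (planting communities of correlated voxels,
    i.e. high-degree hub candidates). Raises on a non-positive-definite
    specification.
    """
    if n_timepoints < 30:
        raise ValueError("n_timepoints must be >= 30")
    n = grid.n_gray
    if isinstance(community_spec, np.ndarray):
        corr = np.asarray(community_spec, dtype=float)
        if corr.shape != (n, n):
            raise ValueError("correlation matrix must be n_gray x n_gray")
    else:
        corr = block_correlation_matrix(n, community_spec)
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise ValueError("community_spec is not positive definite") from exc
    rng = np.random.default_rng(seed)
    return [
        chol @ rng.standard_normal((n, n_timepoints)) for _ in range(n_subjects)
    ]


@dataclass
class ExpressionMatrix:
    """Samples x genes expression with sample coordinates and hub labels.

    ``labels`` holds "hub", "nonhub" or "excluded" per sample.
    """

    sample_ids: list[str]
    coords: np.ndarray  # (n_samples, 3) mm
    genes: list[str]
    values: np.ndarray  # (n_samples, n_genes)
    labels: np.ndarray  # object/str array
    informative_genes: list[str] | None = None  # ground truth, if synthetic

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        self.labels = np.asarray(self.labels)
        n_s, n_g = self.values.shape
        if len(self.sample_ids) != n_s or len(self.genes) != n_g:
            raise ValueError("ids/genes must match the value matrix")
        if self.coords.shape != (n_s, 3):
            raise ValueError("coords must be (n_samples, 3)")
        if len(self.labels) != n_s:
            raise ValueError("one label per sample")
        if not np.isfinite(self.values).all():
            raise ValueError("expression values must be finite")

    @property
    def hub_idx(self) -> np.ndarray:
        return np.flatnonzero(self.labels == "hub")

    @property
    def nonhub_idx(self) -> np.ndarray:
        return np.flatnonzero(self.labels == "nonhub")


def _smooth_field(coords: np.ndarray, white: np.ndarray, scale_mm: float) -> np.ndarray:
    """Gaussian-kernel smooth a white field over sample coordinates."""
    from scipy.spatial.distance import cdist

    d = cdist(coords, coords)
    w = np.exp(-0.5 * (d / scale_mm) ** 2)
    sm = w @ white
    sm -= sm.mean(axis=0)
    sd = sm.std(axis=0)
    sd[sd == 0] = 1.0
    return sm / sd


def simulate_expression(
    n_hub: int,
    n_nonhub: int,
    n_genes: int,
    n_informative: int,
    effect: float,
    grid: VoxelGrid,
    spatial_scale: float = 15.0,
    seed: int = 0,
    hub_mask: np.ndarray | None = None,
) -> ExpressionMatrix:
    """Simulate an expression matrix with label-informative genes.

    Hub samples sit at hub-mask voxels when a mask is given (random gray
    voxels otherwise); informative genes are spatially smoothed Gaussian
    fields (length scale ``spatial_scale`` mm) with ``effect`` (in SD units)
    added in hub samples; the remaining genes are label-independent
    unit-variance noise.
    """
    if n_informative > n_genes:
        raise ValueError("n_informative cannot exceed n_genes")
    if min(n_hub, n_nonhub, n_genes) <= 0 or n_informative < 0:
        raise ValueError("counts must be positive")
    rng = np.random.default_rng(seed)
    coords_all = grid.coords_mm()
    if hub_mask is not None:
        hub_pool = np.flatnonzero(np.asarray(hub_mask, dtype=bool))
        non_pool = np.flatnonzero(~np.asarray(hub_mask, dtype=bool))
        if len(hub_pool) == 0 or len(non_pool) == 0:
            raise ValueError("hub mask must split the grid into two nonempty sets")
        hub_vox = rng.choice(hub_pool, size=n_hub, replace=True)
        non_vox = rng.choice(non_pool, size=n_nonhub, replace=True)
    else:
        hub_vox = rng.integers(0, grid.n_gray, size=n_hub)
        non_vox = rng.integers(0, grid.n_gray, size=n_nonhub)
    vox = np.concatenate([hub_vox, non_vox])
    # sub-voxel jitter so no two samples share exact coordinates
    coords = coords_all[vox] + rng.uniform(
        -grid.voxel_size_mm / 4, grid.voxel_size_mm / 4, size=(len(vox), 3)
    )
    labels = np.array(["hub"] * n_hub + ["nonhub"] * n_nonhub)
    is_hub = labels == "hub"

    values = rng.standard_normal((len(vox), n_genes))
    if n_informative > 0:
        white = rng.standard_normal((len(vox), n_informative))
        fields = _smooth_field(coords, white, spatial_scale)
        values[:, :n_informative] = fields
        values[is_hub, :n_informative] += effect
    genes = [f"gene{g:05d}" for g in range(n_genes)]
    return ExpressionMatrix(
        sample_ids=[f"sample{s:05d}" for s in range(len(vox))],
        coords=coords,
        genes=genes,
        values=values,
        labels=labels,
        informative_genes=genes[:n_informative],
    )
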