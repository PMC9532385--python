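"""Voxelwise DerSimonian–Laird random-effects meta-analysis.

Each cohort i contributes a mean map M_i, a variance map SD_i^2 and a
subject count N_i. Per voxel:

    W_i   = N_i / SD_i^2                      (fixed-effect weight)
    Q     = sum W_i M_i^2 - (sum W_i M_i)^2 / sum W_i
    df    = k - 1
    T^2   = max(0, (Q - df) / (sum W - sum W^2 / sum W))
    I^2   = max(0, (Q - df) / Q) * 100        (0 when Q = 0)
    W*_i  = 1 / (SD_i^2 / N_i + T^2)          (random-effects weight)
    M*    = sum W*_i M_i / sum W*_i
    V     = 1 / sum W*_i,  SE = sqrt(V)

The pooled mean is compared with the global mean of the normalized maps
(zero) via Z = M*/SE, and the effect size is Cohen's d = Z / sqrt(k).
T^2 and I^2 are floored at zero (standard truncation of the
method-of-moments estimator).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .glm import CohortSummary


class InsufficientCohortsError(ValueError):
    pass


@dataclass
class MetaResult:
    """Voxelwise random-effects summary across k cohorts."""

    m_star: np.ndarray
    se: np.ndarray
    variance: np.ndarray
    q: np.ndarray
    df: int
    tau2: np.ndarray
    i2: np.ndarray
    k: int
    z: np.ndarray = field(default=None)  # type: ignore[assignment]
    d: np.ndarray = field(default=None)  # type: ignore[assignment]
    weights_original: np.ndarray | None = None
    weights_updated: np.ndarray | None = None


def _meta_arrays(
    means: np.ndarray, variances: np.ndarray, n_subjects: np.ndarray
) -> dict[str, np.ndarray]:
    """Core vectorized computation on (k, n_voxels) stacks."""
    k = means.shape[0]
    w = n_subjects[:, None] / variances  # W_i
    sw = w.sum(axis=0)
    swm = (w * means).sum(axis=0)
    q = (w * means**2).sum(axis=0) - swm**2 / sw
    df = k - 1
    denom = sw - (w**2).sum(axis=0) / sw
    with np.errstate(invalid="ignore", divide="ignore"):
        tau2 = np.maximum(0.0, (q - df) / denom)
        i2 = np.where(q > 0, np.maximum(0.0, (q - df) / q) * 100.0, 0.0)
    w_star = 1.0 / (variances / n_subjects[:, None] + tau2[None, :])
    sw_star = w_star.sum(axis=0)
    m_star = (w_star * means).sum(axis=0) / sw_star
    v = 1.0 / sw_star
    return {
        "m_star": m_star,
        "variance": v,
        "se": np.sqrt(v),
        "q": q,
        "tau2": tau2,
        "i2": i2,
        "w": w,
        "w_star": w_star,
    }


def random_effects_meta(summaries: list[CohortSummary]) -> MetaResult:
    """Pool cohort summaries voxelwise; NaN-flags voxels where any cohort
    variance is non-positive."""
    k = len(summaries)
    if k < 2:
        raise InsufficientCohortsError("need at least 2 cohorts")
    means = np.stack([s.mean_map for s in summaries])
    variances = np.stack([s.variance_map for s in summaries]).astype(float)
    n_subjects = np.array([s.n_subjects for s in summaries], dtype=float)

    bad = (variances <= 0).any(axis=0)
    variances = variances.copy()
    variances[:, bad] = 1.0  # placeholder; flagged NaN below
    out = _meta_arrays(means, variances, n_subjects)
    for key in ("m_star", "variance", "se", "q", "tau2", "i2"):
        out[key][bad] = np.nan
    return MetaResult(
        m_star=out["m_star"],
        se=out["se"],
        variance=out["variance"],
        q=out["q"],
        df=k - 1,
        tau2=out["tau2"],
        i2=out["i2"],
        k=k,
        weights_original=out["w"],
        weights_updated=out["w_star"],
    )


def effect_size(result: MetaResult) -> MetaResult:
    """Fill Z = M*/SE and Cohen's d = Z/sqrt(k); SE = 0 flags NaN."""
    se = result.se
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(se > 0, result.m_star / se, np.nan)
    result.z = z
    result.d = z / np.sqrt(result.k)
    return result


def meta_z(means: np.ndarray, variances: np.ndarray, n_subjects: np.ndarray) -> np.ndarray:
    """Fast path: Z map only, from (k, n) stacks (used in permutation loops)."""
    out = _meta_arrays(means, variances, np.asarray(n_subjects, dtype=float))
    return out["m_star"] / out["se"]
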