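"""Per-cohort general linear model.

Each cohort's normalized FCS (or Fisher-z) maps are adjusted for age and
sex voxelwise: ``y = b0 + b_age*(age - mean age) + b_sex*(sex - mean sex)
+ e``. Because both covariates are centered, the intercept ``b0`` is the
covariate-adjusted cohort mean; the residual variance (unbiased, df = N - p)
is the cohort variance map. Together with the subject count these summaries
feed the random-effects meta-analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger("metahub")


class InsufficientSubjectsError(ValueError):
    pass


@dataclass
class CohortSummary:
    """Meta-analysis input for one cohort: mean map M_i, variance map SD_i^2,
    subject count N_i."""

    cohort_id: str
    mean_map: np.ndarray
    variance_map: np.ndarray
    n_subjects: int
    mean_age: float = float("nan")

    def __post_init__(self) -> None:
        self.mean_map = np.asarray(self.mean_map, dtype=float)
        self.variance_map = np.asarray(self.variance_map, dtype=float)
        if self.mean_map.shape != self.variance_map.shape:
            raise ValueError("mean and variance maps must share shape")
        if np.any(self.variance_map < 0):
            raise ValueError("variance map must be non-negative")
        if self.n_subjects < 2:
            raise InsufficientSubjectsError("n_subjects must be >= 2")


@dataclass
class GlmCoefficients:
    beta0: np.ndarray
    beta_age: np.ndarray | None
    beta_sex: np.ndarray | None


def fit_cohort_glm(
    subject_maps: np.ndarray,
    ages: np.ndarray,
    sexes: np.ndarray,
    cohort_id: str = "cohort",
) -> tuple[CohortSummary, GlmCoefficients]:
    """Fit the voxelwise age/sex GLM for one cohort.

    ``subject_maps`` is (N, n_voxels); ``sexes`` may be any binary coding
    and is recoded to +/-0.5 then centered at the cohort mean. Constant
    covariate columns (single-sex cohorts, identical ages) are dropped with
    a warning. Returns the cohort summary (intercept map, unbiased residual
    variance with df = N - p, N) and the fitted coefficients.
    """
    y = np.asarray(subject_maps, dtype=float)
    ages = np.asarray(ages, dtype=float)
    sexes = np.asarray(sexes, dtype=float)
    if y.ndim != 2:
        raise ValueError("subject_maps must be (n_subjects, n_voxels)")
    n = y.shape[0]
    if n < 2:
        raise InsufficientSubjectsError("need at least 2 subjects")
    if not np.isfinite(ages).all():
        raise ValueError("ages must be finite")
    if len(ages) != n or len(sexes) != n:
        raise ValueError("one age and sex per subject")

    uniq = np.unique(sexes)
    if len(uniq) > 2:
        raise ValueError("sex must be binary")
    sex_pm = np.where(sexes == uniq.max(), 0.5, -0.5) if len(uniq) == 2 else None

    cols = [np.ones(n)]
    keep_age = np.ptp(ages) > 0
    if keep_age:
        cols.append(ages - ages.mean())
    else:
        logger.warning("%s: constant age column dropped", cohort_id)
    keep_sex = sex_pm is not None
    if keep_sex:
        cols.append(sex_pm - sex_pm.mean())
    else:
        logger.warning("%s: constant sex column dropped", cohort_id)
    X = np.column_stack(cols)
    p = X.shape[1]
    if n <= p:
        raise InsufficientSubjectsError(
            f"{cohort_id}: {n} subjects cannot identify {p} coefficients"
        )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    var = (resid**2).sum(axis=0) / (n - p)

    i = 1
    beta_age = None
    beta_sex = None
    if keep_age:
        beta_age = beta[i]
        i += 1
    if keep_sex:
        beta_sex = beta[i]
    summary = CohortSummary(
        cohort_id=cohort_id,
        mean_map=beta[0],
        variance_map=var,
        n_subjects=n,
        mean_age=float(ages.mean()),
    )
    return summary, GlmCoefficients(beta0=beta[0], beta_age=beta_age, beta_sex=beta_sex)
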