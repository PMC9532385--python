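import numpy as np
import pytest

from metahub import make_grid, simulate_cohort_maps
from metahub.glm import CohortSummary, InsufficientSubjectsError, fit_cohort_glm
from metahub.meta import (
    InsufficientCohortsError,
    effect_size,
    random_effects_meta,
)
from metahub.synthetic import GroundTruth


class TestCohortGlm:
    def test_reduces_to_sample_moments_without_covariates(self, rng):
        maps = rng.standard_normal((15, 40))
        ages = np.full(15, 25.0)  # constant -> dropped
        sexes = np.zeros(15)  # constant -> dropped
        summary, coefs = fit_cohort_glm(maps, ages, sexes)
        assert np.allclose(summary.mean_map, maps.mean(axis=0))
        assert np.allclose(summary.variance_map, maps.var(axis=0, ddof=1))
        assert coefs.beta_age is None and coefs.beta_sex is None

    def test_single_sex_cohort_fits(self, rng):
        maps = rng.standard_normal((10, 5))
        summary, coefs = fit_cohort_glm(
            maps, rng.uniform(18, 36, 10), np.ones(10)
        )
        assert summary.n_subjects == 10
        assert coefs.beta_sex is None

    def test_matches_normal_equations_oracle(self, rng):
        n, v = 20, 50
        maps = rng.standard_normal((n, v))
        ages = rng.uniform(18, 36, n)
        sexes = rng.integers(0, 2, n).astype(float)
        summary, coefs = fit_cohort_glm(maps, ages, sexes)
        sex_pm = np.where(sexes == 1, 0.5, -0.5)
        X = np.column_stack(
            [np.ones(n), ages - ages.mean(), sex_pm - sex_pm.mean()]
        )
        beta = np.linalg.solve(X.T @ X, X.T @ maps)
        resid = maps - X @ beta
        assert np.allclose(coefs.beta0, beta[0], atol=1e-10)
        assert np.allclose(coefs.beta_age, beta[1], atol=1e-10)
        assert np.allclose(coefs.beta_sex, beta[2], atol=1e-10)
        assert np.allclose(
            summary.variance_map, (resid**2).sum(axis=0) / (n - 3), atol=1e-10
        )

    def test_centering_invariance(self, rng):
        maps = rng.standard_normal((12, 8))
        ages = rng.uniform(18, 36, 12)
        sexes = rng.integers(0, 2, 12).astype(float)
        s1, _ = fit_cohort_glm(maps, ages, sexes)
        s2, _ = fit_cohort_glm(maps, ages + 7.0, sexes)
        assert np.allclose(s1.mean_map, s2.mean_map)
        assert np.allclose(s1.variance_map, s2.variance_map)

    def test_beta_age_recovery_unbiased(self):
        grid = make_grid((3, 3, 3))
        beta_age = 0.05
        truth = GroundTruth(
            true_mean_map=np.zeros(grid.n_gray),
            tau2=0.0,
            sigma_within=0.5,
            beta_age=beta_age,
            beta_sex=0.0,
            hub_mask_true=np.zeros(grid.n_gray, dtype=bool),
        )
        estimates = []
        for rep in range(200):
            (c,) = simulate_cohort_maps(grid, truth, [20], seed=3000 + rep)
            _, coefs = fit_cohort_glm(c.subject_maps, c.ages, c.sexes)
            estimates.append(coefs.beta_age.mean())
        estimates = np.asarray(estimates)
        se = estimates.std(ddof=1) / np.sqrt(len(estimates))
        assert abs(estimates.mean() - beta_age) < 2 * se + 1e-12

    def test_too_few_subjects_rejected(self, rng):
        with pytest.raises(InsufficientSubjectsError):
            fit_cohort_glm(rng.standard_normal((1, 4)), [20.0], [0.0])


def summaries_from(means, variances, ns):
    return [
        CohortSummary(f"c{i}", np.atleast_1d(m), np.atleast_1d(v), n)
        for i, (m, v, n) in enumerate(zip(means, variances, ns))
    ]


class TestRandomEffectsMeta:
    def test_hand_worked_three_cohorts(self):
        """k=3, M=(1,2,3), SD^2=1, N=10: Q=20, T^2=0.9, I^2=90, M*=2, d=2."""
        res = effect_size(
            random_effects_meta(summaries_from([1, 2, 3], [1, 1, 1], [10, 10, 10]))
        )
        assert res.q[0] == pytest.approx(20.0, abs=1e-10)
        assert res.df == 2
        assert res.tau2[0] == pytest.approx(0.9, abs=1e-10)
        assert res.i2[0] == pytest.approx(90.0, abs=1e-10)
        assert res.m_star[0] == pytest.approx(2.0, abs=1e-10)
        assert res.se[0] == pytest.approx(1 / np.sqrt(3), abs=1e-10)
        assert res.z[0] == pytest.approx(2 * np.sqrt(3), abs=1e-10)
        assert res.d[0] == pytest.approx(2.0, abs=1e-10)
        assert np.allclose(res.weights_updated, 1.0)

    def test_homogeneity_limit(self):
        res = random_effects_meta(
            summaries_from([1.5, 1.5, 1.5, 1.5], [2, 2, 2, 2], [8, 8, 8, 8])
        )
        assert res.q[0] == pytest.approx(0.0, abs=1e-10)
        assert res.tau2[0] == 0.0
        assert res.i2[0] == 0.0
        assert res.m_star[0] == pytest.approx(1.5)
        assert res.se[0] == pytest.approx(np.sqrt(1 / (4 * 8 / 2)))

    def test_zero_tau2_equals_fixed_effect(self, rng):
        means = rng.normal(1.0, 0.001, 5)
        variances = rng.uniform(0.5, 2.0, 5)
        ns = rng.integers(5, 30, 5)
        res = random_effects_meta(summaries_from(means, variances, ns))
        if res.tau2[0] == 0.0:
            w = ns / variances
            assert res.m_star[0] == pytest.approx((w * means).sum() / w.sum())

    def test_scale_equivariance(self, rng):
        means = rng.normal(0, 1, 6)
        variances = rng.uniform(0.5, 2, 6)
        ns = rng.integers(5, 40, 6)
        r1 = effect_size(random_effects_meta(summaries_from(means, variances, ns)))
        c = 3.7
        r2 = effect_size(
            random_effects_meta(summaries_from(c * means, c**2 * variances, ns))
        )
        assert r2.m_star[0] == pytest.approx(c * r1.m_star[0])
        assert r2.se[0] == pytest.approx(c * r1.se[0])
        assert r2.tau2[0] == pytest.approx(c**2 * r1.tau2[0])
        assert r2.z[0] == pytest.approx(r1.z[0])
        assert r2.i2[0] == pytest.approx(r1.i2[0])

    def test_cohort_order_invariance(self, rng):
        means = rng.normal(0, 1, 7)
        variances = rng.uniform(0.5, 2, 7)
        ns = rng.integers(5, 40, 7)
        r1 = random_effects_meta(summaries_from(means, variances, ns))
        perm = rng.permutation(7)
        r2 = random_effects_meta(
            summaries_from(means[perm], variances[perm], ns[perm])
        )
        assert r2.m_star[0] == pytest.approx(r1.m_star[0])
        assert r2.q[0] == pytest.approx(r1.q[0])

    def test_insufficient_cohorts(self):
        with pytest.raises(InsufficientCohortsError):
            random_effects_meta(summaries_from([1.0], [1.0], [10]))

    def test_tau2_recovery_and_ci_coverage(self):
        """k=60 cohorts, tau2=0.04: voxel-average T^2 within 15% of truth and
        95% CI covers the true mean in 93-97% of 500 voxels."""
        k, n_vox, n_sub, tau2, sigma = 60, 500, 20, 0.04, 1.0
        rng = np.random.default_rng(77)
        u = rng.normal(0, np.sqrt(tau2), (k, n_vox))
        subj = rng.normal(0, sigma, (k, n_sub, n_vox))
        means = u + subj.mean(axis=1)
        variances = subj.var(axis=1, ddof=1)
        summaries = [
            __import__("metahub").glm.CohortSummary(f"c{i}", means[i], variances[i], n_sub)
            for i in range(k)
        ]
        res = random_effects_meta(summaries)
        assert abs(res.tau2.mean() - tau2) / tau2 < 0.15
        covered = np.abs(res.m_star) <= 1.96 * res.se
        assert 0.93 <= covered.mean() <= 0.97

    def test_homogeneous_simulation_low_i2(self):
        """With tau2=0, I^2 > 50% at fewer than 5% of voxels."""
        k, n_vox, n_sub = 20, 1000, 15
        rng = np.random.default_rng(5)
        subj = rng.normal(0, 1.0, (k, n_sub, n_vox))
        summaries = [
            CohortSummary(f"c{i}", subj[i].mean(axis=0), subj[i].var(axis=0, ddof=1), n_sub)
            for i in range(k)
        ]
        res = random_effects_meta(summaries)
        assert (res.i2 > 50).mean() < 0.05

    def test_nonpositive_variance_flagged_nan(self):
        summaries = summaries_from([[1.0, 1.0], [2.0, 2.0]], [[1.0, 0.0], [1.0, 1.0]], [10, 10])
        res = random_effects_meta(summaries)
        assert np.isnan(res.m_star[1]) and np.isfinite(res.m_star[0])
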