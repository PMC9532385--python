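import numpy as np
import pandas as pd
import pytest

from metahub import (
    assign_parcel_hubs,
    geneset_pc1,
    label_samples,
    make_grid,
    simulate_expression,
    svm_topn_sweep,
    train_boosted_protocol,
    trajectory,
    trajectory_difference,
)

FAST = dict(cv_folds=3, max_rounds=20, patience=5)


@pytest.fixture(scope="module")
def expr_grid():
    return make_grid((6, 6, 6), voxel_size_mm=3.0, n_networks=4)


@pytest.fixture(scope="module")
def planted_expr(expr_grid):
    return simulate_expression(
        n_hub=80, n_nonhub=120, n_genes=20, n_informative=5,
        effect=3.0, grid=expr_grid, seed=21,
    )


@pytest.fixture(scope="module")
def planted_report(planted_expr):
    return train_boosted_protocol(
        planted_expr, n_train_per_class=40, n_repetitions=8, seed=3, **FAST
    )


class TestLabelSamples:
    def test_hub_nonhub_excluded_assignment(self, expr_grid):
        hub = np.zeros(expr_grid.n_gray, dtype=bool)
        hub[0] = True  # voxel (0, 0, 0) -> mm (0, 0, 0)
        coords = np.array(
            [
                [0.0, 0.0, 0.0],  # exactly the hub voxel
                [1.2, -1.2, 0.9],  # rounds to the hub voxel
                [6.0, 6.0, 6.0],  # gray, not hub
                [500.0, 0.0, 0.0],  # outside the grid
            ]
        )
        labels = label_samples(coords, hub, expr_grid)
        assert list(labels) == ["hub", "hub", "nonhub", "excluded"]

    def test_nonfinite_coordinates_rejected(self, expr_grid):
        hub = np.zeros(expr_grid.n_gray, dtype=bool)
        with pytest.raises(ValueError):
            label_samples(np.array([[np.nan, 0.0, 0.0]]), hub, expr_grid)


class TestBoostedProtocol:
    def test_planted_signal_classified_and_ranked(self, planted_expr, planted_report):
        rep = planted_report
        assert rep.mean_accuracy > 90.0
        top5 = set(rep.contributions.nlargest(5).index)
        assert top5 == set(planted_expr.informative_genes)
        assert np.all((rep.sensitivity >= 0) & (rep.sensitivity <= 100))
        assert np.all((rep.specificity >= 0) & (rep.specificity <= 100))

    def test_label_free_data_at_chance(self, expr_grid):
        expr = simulate_expression(
            n_hub=80, n_nonhub=120, n_genes=10, n_informative=0,
            effect=0.0, grid=expr_grid, seed=5,
        )
        rep = train_boosted_protocol(
            expr, n_train_per_class=40, n_repetitions=10, seed=1, **FAST
        )
        assert abs(rep.mean_accuracy - 50.0) < 12.0

    def test_deterministic_under_seed(self, planted_expr):
        a = train_boosted_protocol(
            planted_expr, n_train_per_class=40, n_repetitions=2, seed=9, **FAST
        )
        b = train_boosted_protocol(
            planted_expr, n_train_per_class=40, n_repetitions=2, seed=9, **FAST
        )
        assert np.array_equal(a.accuracy, b.accuracy)
        assert a.contributions.equals(b.contributions)

    def test_label_override_breaks_signal(self, planted_expr):
        rng = np.random.default_rng(2)
        permuted = rng.permutation(planted_expr.labels)
        rep = train_boosted_protocol(
            planted_expr, n_train_per_class=40, n_repetitions=8,
            seed=4, labels=permuted, **FAST,
        )
        assert abs(rep.mean_accuracy - 50.0) < 12.0

    def test_class_too_small_rejected(self, planted_expr):
        with pytest.raises(ValueError):
            train_boosted_protocol(planted_expr, n_train_per_class=80, **FAST)

    def test_correct_rates_in_unit_interval(self, planted_report):
        rates = planted_report.correct_rates.dropna()
        assert len(rates) > 0
        assert ((rates >= 0) & (rates <= 1)).all()


class TestSvmSweep:
    def test_planted_signal_high_accuracy(self, planted_expr, planted_report):
        accs = svm_topn_sweep(
            planted_expr,
            planted_report.contributions,
            planted_report.correct_rates,
            n_range=[5, 10],
            task="easiest",
            cv_folds=5,
            seed=0,
        )
        assert list(accs.index) == [5, 10]
        assert (accs > 85.0).all()

    def test_task_and_range_guards(self, planted_expr, planted_report):
        with pytest.raises(ValueError):
            svm_topn_sweep(
                planted_expr, planted_report.contributions,
                planted_report.correct_rates, n_range=[5], task="middling",
            )
        with pytest.raises(ValueError):
            svm_topn_sweep(
                planted_expr, planted_report.contributions,
                planted_report.correct_rates, n_range=[999], cv_folds=5,
            )


class TestGenesetPc1:
    def test_rank_one_matrix_fully_explained(self):
        rng = np.random.default_rng(0)
        loading = rng.random(6) + 0.5
        score = rng.standard_normal(40)
        values = np.outer(score, loading)
        expr = _expr_from_values(values)
        gs = geneset_pc1(expr, expr.genes)
        assert gs.explained_variance == pytest.approx(1.0)
        assert gs.scores.min() == 0.0 and gs.scores.max() == 1.0

    def test_sign_aligned_to_mean_expression(self):
        rng = np.random.default_rng(1)
        values = rng.standard_normal((30, 4)) + np.linspace(0, 2, 30)[:, None]
        expr = _expr_from_values(values)
        gs = geneset_pc1(expr, expr.genes)
        assert np.corrcoef(gs.scores, values.mean(axis=1))[0, 1] > 0

    def test_eigen_oracle_single_gene(self):
        rng = np.random.default_rng(2)
        values = rng.standard_normal((25, 3))
        expr = _expr_from_values(values)
        gs = geneset_pc1(expr, [expr.genes[1]])
        g = values[:, 1]
        expected = (g - g.min()) / (g.max() - g.min())
        assert np.allclose(gs.scores, expected) or np.allclose(
            gs.scores, 1.0 - expected
        )

    def test_missing_genes_rejected(self):
        expr = _expr_from_values(np.random.default_rng(3).standard_normal((10, 2)))
        with pytest.raises(ValueError):
            geneset_pc1(expr, ["absent_gene"])


def _expr_from_values(values):
    from metahub.synthetic import ExpressionMatrix

    n_s, n_g = values.shape
    return ExpressionMatrix(
        sample_ids=[f"s{i}" for i in range(n_s)],
        coords=np.zeros((n_s, 3)),
        genes=[f"g{j}" for j in range(n_g)],
        values=values,
        labels=np.array(["nonhub"] * n_s),
    )


class TestTrajectory:
    def test_recovers_smooth_curve_in_log_age(self):
        rng = np.random.default_rng(4)
        days = np.exp(rng.uniform(np.log(56), np.log(14000), 400))
        x = np.log2(days)
        truth = 0.5 + 0.3 * np.sin((x - x.min()) / (x.max() - x.min()) * np.pi)
        scores = truth + 0.03 * rng.standard_normal(len(x))
        curve = trajectory(days, scores, frac=0.3)
        x_grid = curve["log2_days"].to_numpy()
        expected = 0.5 + 0.3 * np.sin((x_grid - x.min()) / (x.max() - x.min()) * np.pi)
        interior = (x_grid > x.min() + 0.5) & (x_grid < x.max() - 0.5)
        rmse = np.sqrt(np.mean((curve["score"].to_numpy()[interior] - expected[interior]) ** 2))
        assert rmse < 0.02
        assert len(curve) == 100

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            trajectory([100, 200, 300], [0.1, 0.2, 0.3])

    def test_difference_identical_curves_zero(self):
        curve = pd.DataFrame({"log2_days": np.linspace(6, 13, 50), "score": np.linspace(0, 1, 50)})
        diff = trajectory_difference(curve, curve.copy())
        assert np.allclose(diff["difference"], 0.0)
        assert not diff["exceeds_mad"].any()

    def test_difference_mad_oracle_and_flags(self):
        grid = np.linspace(6, 13, 10)
        hub = pd.DataFrame({"log2_days": grid, "score": np.full(10, 0.8)})
        non = pd.DataFrame({"log2_days": grid, "score": np.full(10, 0.5)})
        regional = pd.DataFrame(
            {"r1": np.full(10, 0.1), "r2": np.full(10, 0.5), "r3": np.full(10, 0.9)}
        )
        diff = trajectory_difference(hub, non, regional)
        assert np.allclose(diff["mad"], 0.4)  # median |x - 0.5| of (0.1, 0.5, 0.9)
        assert not diff["exceeds_mad"].any()  # |0.3| <= 0.4
        hub2 = pd.DataFrame({"log2_days": grid, "score": np.full(10, 1.0)})
        diff2 = trajectory_difference(hub2, non, regional)
        assert diff2["exceeds_mad"].all()  # |0.5| > 0.4

    def test_mismatched_grids_rejected(self):
        a = pd.DataFrame({"log2_days": [6.0, 7.0], "score": [0.0, 1.0]})
        b = pd.DataFrame({"log2_days": [6.0, 8.0], "score": [0.0, 1.0]})
        with pytest.raises(ValueError):
            trajectory_difference(a, b)


class TestParcelHubs:
    def test_majority_rule_strict(self):
        parcels = np.array([1] * 10 + [2] * 10 + [3] * 10)
        hub = np.zeros(30, dtype=bool)
        hub[:6] = True  # parcel 1: 60%
        hub[10:15] = True  # parcel 2: exactly 50%
        assert assign_parcel_hubs(parcels, hub) == {1}

    def test_zero_label_ignored(self):
        parcels = np.array([0, 0, 0, 4, 4])
        hub = np.array([True, True, True, True, True])
        assert assign_parcel_hubs(parcels, hub) == {4}

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            assign_parcel_hubs(np.zeros(3, dtype=int), np.zeros(4, dtype=bool))
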