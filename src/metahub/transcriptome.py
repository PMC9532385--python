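"""Transcriptomic association of connectome hubs.

Expression samples are labeled hub / non-hub by their coordinates against
the hub identification map, and a balanced gradient-boosted-tree protocol
is trained repeatedly to distinguish the two classes from gene expression:
each repetition draws an equal number of training samples per class, picks
the boosting length by cross-validation with early stopping, and tests on
the held-out samples. Gene contributions (gain importance) accumulated
over repetitions rank genes; the top genes feed a radial-basis SVM sweep
on the easiest / hardest non-hub subsets. Gene sets are summarized by
their expression PC1, developmental trajectories by lowess smoothing
against log2 post-conceptional days with a median-absolute-deviation band.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .grid import VoxelGrid
from .synthetic import ExpressionMatrix

logger = logging.getLogger("metahub")


def label_samples(
    coords: np.ndarray, hub_mask: np.ndarray, grid: VoxelGrid
) -> np.ndarray:
    """Label sample coordinates as hub / nonhub / excluded.

    Each sample maps to its nearest voxel (via the grid affine); samples
    landing outside the grid or the gray mask are excluded, samples on a
    hub voxel are "hub", remaining in-mask samples are "nonhub".
    """
    coords = np.asarray(coords, dtype=float)
    if not np.isfinite(coords).all():
        raise ValueError("coordinates must be finite")
    inv = np.linalg.inv(grid.affine)
    homo = np.c_[coords, np.ones(len(coords))]
    ijk = np.rint((homo @ inv.T)[:, :3]).astype(int)
    labels = np.full(len(coords), "excluded", dtype=object)
    dims = np.asarray(grid.dims)
    inside = np.all((ijk >= 0) & (ijk < dims), axis=1)
    # flat gray-mask lookup
    gray_flat = grid.gray_mask.ravel(order="C")
    hub_full = grid.embed(np.asarray(hub_mask, dtype=float)) > 0.5
    hub_flat = hub_full.ravel(order="C")
    flat = np.ravel_multi_index(ijk[inside].T, grid.dims, order="C")
    lab_in = np.where(hub_flat[flat], "hub", np.where(gray_flat[flat], "nonhub", "excluded"))
    labels[inside] = lab_in
    return labels.astype(str)


@dataclass
class ClassifierReport:
    """Held-out performance and gene contributions of the boosted protocol."""

    sensitivity: np.ndarray  # % per repetition
    specificity: np.ndarray
    accuracy: np.ndarray
    contributions: pd.Series  # mean gain importance per gene
    correct_rates: pd.Series  # per-sample correct-classification rate
    n_repetitions: int
    seed: int
    per_rep_contributions: np.ndarray | None = field(default=None, repr=False)

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracy.mean())

    @property
    def log_contributions(self) -> pd.Series:
        """Contributions on a log10(1 + gain) scale."""
        return np.log10(1.0 + self.contributions)


def train_boosted_protocol(
    expr: ExpressionMatrix,
    n_train_per_class: int = 300,
    n_repetitions: int = 1000,
    cv_folds: int = 30,
    max_rounds: int = 1500,
    patience: int = 50,
    learning_rate: float = 0.05,
    seed: int = 0,
    labels: np.ndarray | None = None,
) -> ClassifierReport:
    """Balanced boosted-tree classification of hub vs non-hub samples.

    Per repetition: draw ``n_train_per_class`` samples per class for
    training and test on the rest; pick the boosting length by
    ``cv_folds``-fold cross-validation with ``patience``-round early
    stopping (binary logistic loss, learning rate ``learning_rate``, at
    most ``max_rounds`` rounds); record held-out sensitivity, specificity
    and accuracy (%), accumulate gain importances and each held-out
    sample's correctness. ``labels`` overrides the matrix's own labels
    (e.g. permuted or surrogate labelings).
    """
    lab = np.asarray(labels if labels is not None else expr.labels)
    hub_idx = np.flatnonzero(lab == "hub")
    non_idx = np.flatnonzero(lab == "nonhub")
    if len(hub_idx) <= n_train_per_class or len(non_idx) <= n_train_per_class:
        raise ValueError(
            "each class must exceed n_train_per_class so a test set remains"
        )
    X = expr.values
    y = np.zeros(len(lab))
    y[hub_idx] = 1.0
    rng = np.random.default_rng(seed)
    n_genes = X.shape[1]
    sens = np.empty(n_repetitions)
    spec = np.empty(n_repetitions)
    acc = np.empty(n_repetitions)
    gain_sum = np.zeros(n_genes)
    per_rep_gain = np.zeros((n_repetitions, n_genes))
    tested = np.zeros(len(lab))
    correct = np.zeros(len(lab))
    params = {
        "objective": "binary:logistic",
        "eta": learning_rate,
        "tree_method": "hist",
        "nthread": 1,
        "verbosity": 0,
    }
    feat_names = [f"f{g}" for g in range(n_genes)]
    for rep in range(n_repetitions):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        r = np.random.default_rng(rep_seed)
        tr_hub = r.choice(hub_idx, size=n_train_per_class, replace=False)
        tr_non = r.choice(non_idx, size=n_train_per_class, replace=False)
        train = np.concatenate([tr_hub, tr_non])
        test = np.setdiff1d(np.concatenate([hub_idx, non_idx]), train)
        dtrain = xgb.DMatrix(X[train], label=y[train], feature_names=feat_names)
        # cross-validated choice of the boosting length: average the per-round
        # validation loss across folds (early-stopped) and take its minimum
        skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=rep_seed)
        curves = []
        for tr_f, va_f in skf.split(X[train], y[train]):
            dtr = xgb.DMatrix(X[train][tr_f], label=y[train][tr_f])
            dva = xgb.DMatrix(X[train][va_f], label=y[train][va_f])
            evals_result: dict = {}
            xgb.train(
                {**params, "seed": rep_seed},
                dtr,
                num_boost_round=max_rounds,
                evals=[(dva, "val")],
                early_stopping_rounds=patience,
                evals_result=evals_result,
                verbose_eval=False,
            )
            curves.append(np.asarray(evals_result["val"]["logloss"]))
        n_common = min(len(c) for c in curves)
        mean_loss = np.mean([c[:n_common] for c in curves], axis=0)
        best_rounds = int(np.argmin(mean_loss)) + 1
        booster = xgb.train(
            {**params, "seed": rep_seed}, dtrain, num_boost_round=best_rounds
        )
        dtest = xgb.DMatrix(X[test], feature_names=feat_names)
        prob = booster.predict(dtest)
        pred = prob > 0.5
        truth = y[test] > 0.5
        ok = pred == truth
        tp = (pred & truth).sum()
        tn = (~pred & ~truth).sum()
        sens[rep] = 100.0 * tp / truth.sum()
        spec[rep] = 100.0 * tn / (~truth).sum()
        acc[rep] = 100.0 * ok.mean()
        tested[test] += 1
        correct[test] += ok
        scores = booster.get_score(importance_type="gain")
        for name, g in scores.items():
            per_rep_gain[rep, int(name[1:])] = g
        gain_sum += per_rep_gain[rep]
    with np.errstate(invalid="ignore"):
        rates = np.where(tested > 0, correct / np.maximum(tested, 1), np.nan)
    return ClassifierReport(
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        contributions=pd.Series(gain_sum / n_repetitions, index=expr.genes),
        correct_rates=pd.Series(rates, index=expr.sample_ids),
        n_repetitions=n_repetitions,
        seed=seed,
        per_rep_contributions=per_rep_gain,
    )


def svm_topn_sweep(
    expr: ExpressionMatrix,
    contributions: pd.Series,
    correct_rates: pd.Series,
    n_range: range | list[int] = range(100, 301, 10),
    task: str = "easiest",
    cv_folds: int | None = None,
    seed: int = 0,
    labels: np.ndarray | None = None,
) -> pd.Series:
    """Accuracy of a radial-basis SVM on the top-n contributing genes.

    All hub samples are paired with the |hub| non-hub samples that were
    easiest (highest correct-classification rate in the boosted protocol)
    or hardest to classify; for each ``n`` the top-n genes by contribution
    are standardized and evaluated by stratified cross-validation
    (``cv_folds`` defaults to leave-one-pair-out capped at the hub count).
    Rate ties are broken by sample id.
    """
    if task not in ("easiest", "hardest"):
        raise ValueError("task must be 'easiest' or 'hardest'")
    lab = np.asarray(labels if labels is not None else expr.labels)
    hub_idx = np.flatnonzero(lab == "hub")
    non_idx = np.flatnonzero(lab == "nonhub")
    n_hub = len(hub_idx)
    if len(non_idx) < n_hub:
        raise ValueError("need at least as many non-hub as hub samples")
    rates = correct_rates.to_numpy()[non_idx]
    ids = np.asarray(expr.sample_ids, dtype=object)[non_idx]
    order = np.lexsort((ids, -rates if task == "easiest" else rates))
    chosen_non = non_idx[order[:n_hub]]
    samples = np.concatenate([hub_idx, chosen_non])
    y = np.r_[np.ones(n_hub), np.zeros(n_hub)]

    gene_order = contributions.sort_values(ascending=False, kind="stable").index
    gene_pos = {g: i for i, g in enumerate(expr.genes)}
    folds = cv_folds if cv_folds is not None else min(n_hub, 2 * n_hub)
    accs = {}
    for n in n_range:
        if n > len(gene_order):
            raise ValueError(f"n={n} exceeds gene count {len(gene_order)}")
        cols = [gene_pos[g] for g in gene_order[:n]]
        Xn = expr.values[np.ix_(samples, cols)]
        clf = make_pipeline(StandardScaler(), SVC(kernel="rbf", C=1.0))
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        hits = 0
        for tr, te in skf.split(Xn, y):
            clf.fit(Xn[tr], y[tr])
            hits += (clf.predict(Xn[te]) == y[te]).sum()
        accs[n] = 100.0 * hits / len(y)
    return pd.Series(accs, name=f"svm_accuracy_{task}")


@dataclass
class GeneSetScore:
    name: str
    scores: np.ndarray  # per sample, in [0, 1]
    explained_variance: float  # share of variance captured by PC1


def geneset_pc1(expr: ExpressionMatrix, gene_set: list[str], name: str = "set") -> GeneSetScore:
    """PC1 summary score of a gene set, min-max scaled to [0, 1].

    The component is sign-aligned to correlate positively with the set's
    mean expression so higher scores mean higher transcription.
    """
    present = [g for g in gene_set if g in set(expr.genes)]
    if not present:
        raise ValueError("no gene of the set is present in the matrix")
    if expr.values.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    pos = {g: i for i, g in enumerate(expr.genes)}
    sub = expr.values[:, [pos[g] for g in present]]
    centered = sub - sub.mean(axis=0)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    pc1 = u[:, 0] * s[0]
    mean_expr = sub.mean(axis=1)
    if np.corrcoef(pc1, mean_expr)[0, 1] < 0:
        pc1 = -pc1
    rng_ = pc1.max() - pc1.min()
    scaled = (pc1 - pc1.min()) / rng_ if rng_ > 0 else np.zeros_like(pc1)
    ev = float(s[0] ** 2 / (s**2).sum()) if s.sum() > 0 else 0.0
    return GeneSetScore(name=name, scores=scaled, explained_variance=ev)


def trajectory(
    ages_days: np.ndarray,
    scores: np.ndarray,
    frac: float = 0.5,
    grid_points: int = 100,
) -> pd.DataFrame:
    """Lowess developmental trajectory of a score against log2 days.

    Returns a table with the log2-age grid and the smoothed score.
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess

    ages_days = np.asarray(ages_days, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if len(ages_days) < 5:
        raise ValueError("need at least 5 points")
    x = np.log2(ages_days)
    fit = lowess(scores, x, frac=frac, return_sorted=True)
    grid = np.linspace(x.min(), x.max(), grid_points)
    smoothed = np.interp(grid, fit[:, 0], fit[:, 1])
    return pd.DataFrame({"log2_days": grid, "score": smoothed})


def trajectory_difference(
    curve_hub: pd.DataFrame,
    curve_nonhub: pd.DataFrame,
    regional_values: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Hub minus non-hub trajectory with a MAD band.

    ``regional_values`` is a table (rows: ages on the same log2 grid,
    columns: regions); its per-age median absolute deviation across regions
    gives the band, and ages where |difference| exceeds the MAD are
    flagged. Without regional values the MAD is 0 and nothing is flagged
    unless the difference is nonzero.
    """
    if not np.allclose(curve_hub["log2_days"], curve_nonhub["log2_days"]):
        raise ValueError("curves must share the age grid")
    diff = curve_hub["score"].to_numpy() - curve_nonhub["score"].to_numpy()
    if regional_values is not None:
        vals = regional_values.to_numpy()
        med = np.median(vals, axis=1, keepdims=True)
        mad = np.median(np.abs(vals - med), axis=1)
        if len(mad) != len(diff):
            raise ValueError("regional values must align with the age grid")
    else:
        mad = np.zeros_like(diff)
    return pd.DataFrame(
        {
            "log2_days": curve_hub["log2_days"],
            "difference": diff,
            "mad": mad,
            "exceeds_mad": np.abs(diff) > mad,
        }
    )


def assign_parcel_hubs(parcel_labels: np.ndarray, hub_mask: np.ndarray) -> set[int]:
    """Parcels with more than 50% of their locations inside the hub mask."""
    parcel_labels = np.asarray(parcel_labels)
    hub_mask = np.asarray(hub_mask, dtype=bool)
    if parcel_labels.shape != hub_mask.shape:
        raise ValueError("parcel labels and hub mask must align")
    hubs = set()
    for parcel in np.unique(parcel_labels):
        if parcel == 0:
            continue
        in_parcel = parcel_labels == parcel
        size = int(in_parcel.sum())
        if size == 0:
            logger.warning("parcel %s is empty; skipped", parcel)
            continue
        if hub_mask[in_parcel].sum() / size > 0.5:
            hubs.add(int(parcel))
    return hubs
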