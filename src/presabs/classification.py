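"""Repeated stratified cross-validation and cross-study (LODO) classification.

Five classifier families are supported: random forests (rf), Lasso and
Elastic Net regression used as scorers (lasso, enet), and support vector
machines with linear (lsvm) or RBF (svm) kernel. Random forests use 500
trees, sqrt(n_features) split candidates and the Gini criterion; Lasso and
ENet tune their regularization strength by internal 5-fold stratified CV
over 50 log-uniform values in 10^[-4, -0.5] (ENet additionally over a fixed
l1_ratio grid); SVMs tune the cost over a small log grid. Tuning only ever
sees training-fold data.

AUC and AUPRC are computed from continuous case-scores (class probability
for rf, regression prediction for lasso/enet, decision value for SVMs);
precision, recall and F1 use hard calls (score >= 0.5 on probability-like
scores, sign of the decision value for SVMs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import ElasticNet, Lasso
from sklearn.metrics import average_precision_score, precision_recall_fscore_support
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .profiles_io import LabeledCohort, ProfileError

FAMILIES = ("rf", "lasso", "enet", "lsvm", "svm")
METRICS = ("auc", "auprc", "precision", "recall", "f1")


@dataclass(frozen=True)
class CVConfig:
    """Repeated stratified k-fold configuration (defaults: 10 folds x 20 reps)."""

    k: int = 10
    repetitions: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")


@dataclass
class SplitSet:
    """Explicit reusable train/test partitions: repetitions x folds.

    Built once per dataset and shared across every arm (abundance, each
    threshold, each classifier) so paired fold-level comparisons are valid.
    """

    config: CVConfig
    folds: list[list[tuple[np.ndarray, np.ndarray]]]

    @property
    def repetitions(self) -> int:
        return len(self.folds)

    @property
    def k(self) -> int:
        return len(self.folds[0])


def make_cv_splits(labels: np.ndarray, config: CVConfig) -> SplitSet:
    """Seeded stratified partitions; every repetition is an independent shuffle."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("both classes must be present")
    if counts.min() < config.k:
        raise ValueError(
            f"smallest class has {counts.min()} samples, fewer than k={config.k} folds"
        )
    rep_seeds = np.random.SeedSequence(config.seed).generate_state(config.repetitions)
    folds = []
    for r in range(config.repetitions):
        skf = StratifiedKFold(
            n_splits=config.k, shuffle=True, random_state=int(rep_seeds[r] % 2**31)
        )
        folds.append([(tr.copy(), te.copy()) for tr, te in skf.split(labels, labels)])
    return SplitSet(config=config, folds=folds)


def _default_alpha_grid() -> tuple[float, ...]:
    return tuple(np.logspace(-4, -0.5, 50))


@dataclass(frozen=True)
class ClassifierSpec:
    """A classifier family plus its (tunable) hyperparameters."""

    family: str = "rf"
    n_estimators: int = 500
    alpha_grid: tuple[float, ...] = field(default_factory=_default_alpha_grid)
    l1_ratio_grid: tuple[float, ...] = (0.1, 0.5, 0.7, 0.9, 0.95, 0.99, 1.0)
    cost_grid: tuple[float, ...] = (1e-2, 1e-1, 1.0, 1e1, 1e2, 1e3)
    tuning_folds: int = 5

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown classifier family {self.family!r}; use {FAMILIES}")

    @property
    def probability_like(self) -> bool:
        return self.family in ("rf", "lasso", "enet")


class FittedModel:
    """A fitted classifier exposing continuous case-scores and hard calls."""

    def __init__(self, spec: ClassifierSpec, estimator, scaler, chosen_params: dict):
        self.spec = spec
        self._estimator = estimator
        self._scaler = scaler
        self.chosen_params = chosen_params

    def case_scores(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self._scaler is not None:
            X = self._scaler.transform(X)
        if self.spec.family == "rf":
            return self._estimator.predict_proba(X)[:, 1]
        if self.spec.family in ("lasso", "enet"):
            return self._estimator.predict(X)
        return self._estimator.decision_function(X)

    def hard_calls(self, X: np.ndarray) -> np.ndarray:
        scores = self.case_scores(X)
        if self.spec.probability_like:
            return (scores >= 0.5).astype(int)
        return (scores > 0.0).astype(int)


def _tune(factory, grid: list[dict], X, y, n_folds: int, seed: int) -> dict:
    """Pick the grid point with the best mean AUC over internal stratified CV."""
    if len(grid) == 1:
        return grid[0]
    n_folds = min(n_folds, int(np.bincount(y).min()))
    if n_folds < 2:
        return grid[0]
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed % 2**31)
    splits = list(skf.split(X, y))
    best_params, best_score = grid[0], -np.inf
    for params in grid:
        aucs = []
        for tr, va in splits:
            model = factory(**params)
            model.fit(X[tr], y[tr])
            pred = model.predict(X[va]) if hasattr(model, "predict") else None
            if hasattr(model, "decision_function"):
                pred = model.decision_function(X[va])
            aucs.append(compute_auc(pred, y[va]))
        score = float(np.mean(aucs))
        if score > best_score:
            best_params, best_score = params, score
    return best_params


def fit_model(
    spec: ClassifierSpec, X: np.ndarray, y: np.ndarray, seed: int = 0
) -> FittedModel:
    """Fit one classifier on training data only (tuning included)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("training data must contain both classes")
    seed = int(seed) % 2**31

    if spec.family == "rf":
        est = RandomForestClassifier(
            n_estimators=spec.n_estimators,
            max_features="sqrt",
            criterion="gini",
            random_state=seed,
            n_jobs=1,
        )
        est.fit(X, y)
        return FittedModel(spec, est, None, {})

    scaler = StandardScaler().fit(X)  # penalized/kernel models are scale-sensitive
    Xs = scaler.transform(X)

    if spec.family == "lasso":
        factory = lambda alpha: Lasso(alpha=alpha, max_iter=5000)
        grid = [{"alpha": a} for a in spec.alpha_grid]
    elif spec.family == "enet":
        factory = lambda alpha, l1_ratio: ElasticNet(
            alpha=alpha, l1_ratio=l1_ratio, max_iter=5000
        )
        grid = [
            {"alpha": a, "l1_ratio": r}
            for a in spec.alpha_grid
            for r in spec.l1_ratio_grid
        ]
    else:
        kernel = "linear" if spec.family == "lsvm" else "rbf"
        factory = lambda C: SVC(kernel=kernel, C=C, random_state=seed)
        grid = [{"C": c} for c in spec.cost_grid]

    chosen = _tune(factory, grid, Xs, y, spec.tuning_folds, seed)
    est = factory(**chosen)
    est.fit(Xs, y)
    return FittedModel(spec, est, scaler, chosen)


def compute_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve as P(score_case > score_control) + 0.5 P(tie)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both classes")
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


@dataclass
class FoldScoreMatrix:
    """repetitions x folds matrices of scores, one per metric, for one arm."""

    scores: dict[str, np.ndarray]
    arm: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {m: a.shape for m, a in self.scores.items()}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"inconsistent metric matrix shapes: {shapes}")
        for metric in ("auc", "auprc"):
            if metric in self.scores:
                a = self.scores[metric]
                if np.any(np.isnan(a)) or np.any(a < 0) or np.any(a > 1):
                    raise ValueError(f"{metric} entries must be complete and in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.scores.values())).shape

    def mean(self, metric: str = "auc") -> float:
        return float(self.scores[metric].mean())


def _fold_metrics(scores: np.ndarray, calls: np.ndarray, y: np.ndarray) -> dict:
    precision, recall, f1, _ = precision_recall_fscore_support(
        y, calls, average="binary", pos_label=1, zero_division=0
    )
    return {
        "auc": compute_auc(scores, y),
        "auprc": float(np.clip(average_precision_score(y, scores), 0.0, 1.0)),
        "precision": float(precision),
        "recall": float(recall),
        "f1": float(f1),
    }


def _model_seeds(config: CVConfig, repetitions: int, k: int) -> np.ndarray:
    # distinct per-(repetition, fold) seeds derived from the split seed so that
    # two arms sharing a SplitSet also share model randomness fold-by-fold
    return np.random.SeedSequence([config.seed, 7919]).generate_state(repetitions * k)


def run_cv(
    cohort: LabeledCohort, clf: ClassifierSpec, splits: SplitSet
) -> FoldScoreMatrix:
    """Evaluate one (profile, classifier) arm over a shared SplitSet."""
    X = cohort.profile.values
    y = cohort.labels
    if splits.folds[0][0][0].max() >= X.shape[0]:
        raise ProfileError("SplitSet was built for a larger cohort")
    R, k = splits.repetitions, splits.k
    seeds = _model_seeds(splits.config, R, k)
    mats = {m: np.zeros((R, k)) for m in METRICS}
    for j in range(R):
        for i, (train, test) in enumerate(splits.folds[j]):
            if np.unique(y[train]).size < 2:
                raise ValueError(f"training fold ({j}, {i}) contains a single class")
            try:
                model = fit_model(clf, X[train], y[train], seed=int(seeds[j * k + i]))
            except Exception as exc:
                raise RuntimeError(f"fit failed in repetition {j}, fold {i}: {exc}") from exc
            scores = model.case_scores(X[test])
            calls = model.hard_calls(X[test])
            for m, v in _fold_metrics(scores, calls, y[test]).items():
                mats[m][j, i] = v
    arm = {
        "dataset": cohort.study_id,
        "rank": cohort.profile.rank,
        "profile_type": "presence" if cohort.profile.is_binary else "abundance",
        "classifier": clf.family,
    }
    return FoldScoreMatrix(scores=mats, arm=arm)


def run_lodo(
    datasets: Sequence[LabeledCohort], clf: ClassifierSpec, seed: int = 0
) -> dict[str, dict[str, float]]:
    """Leave-one-dataset-out transfer over a shared taxon universe.

    For each held-out dataset the model is trained on the union of all
    others; taxa absent from a dataset are imputed as 0 (abundance) or
    absent (binary). Returns per-dataset metric dicts keyed by study id.
    """
    if len(datasets) < 2:
        raise ValueError("LODO needs at least two datasets")
    ranks = {d.profile.rank for d in datasets}
    binaries = {d.profile.is_binary for d in datasets}
    if len(ranks) != 1 or len(binaries) != 1:
        raise ProfileError("datasets must share rank and profile type")
    universe: dict[str, int] = {}
    lineages: dict[str, str] = {}
    for d in datasets:
        for t in d.profile.taxa:
            key = t.source_string
            canonical = "|".join(n for n in t.names if n is not None)
            if key in lineages and lineages[key] != canonical:
                raise ProfileError(f"conflicting lineages for identifier {key!r}")
            lineages[key] = canonical
            universe.setdefault(key, len(universe))
    n_feat = len(universe)

    aligned = []
    for d in datasets:
        X = np.zeros((d.profile.n_samples, n_feat))
        cols = [universe[t.source_string] for t in d.profile.taxa]
        X[:, cols] = d.profile.values
        aligned.append(X)

    seeds = np.random.SeedSequence([seed, 104729]).generate_state(len(datasets))
    results: dict[str, dict[str, float]] = {}
    for held_out in range(len(datasets)):
        X_train = np.vstack([aligned[i] for i in range(len(datasets)) if i != held_out])
        y_train = np.concatenate(
            [datasets[i].labels for i in range(len(datasets)) if i != held_out]
        )
        model = fit_model(clf, X_train, y_train, seed=int(seeds[held_out]))
        X_test = aligned[held_out]
        y_test = datasets[held_out].labels
        results[datasets[held_out].study_id] = _fold_metrics(
            model.case_scores(X_test), model.hard_calls(X_test), y_test
        )
    return results


def write_fold_scores(fsm: FoldScoreMatrix, path: str | Path) -> None:
    """Write the long-format score TSV (metric, repetition, fold, value)."""
    R, k = fsm.shape
    rows = []
    for metric, mat in fsm.scores.items():
        for j in range(R):
            for i in range(k):
                rows.append((metric, j, i, repr(float(mat[j, i]))))
    df = pd.DataFrame(rows, columns=["metric", "repetition", "fold", "value"])
    for key, val in fsm.arm.items():
        df[key] = val
    df.to_csv(path, sep="\t", index=False)


def read_fold_scores(path: str | Path) -> FoldScoreMatrix:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    mats = {}
    for metric, grp in df.groupby("metric"):
        R = int(grp["repetition"].max()) + 1
        k = int(grp["fold"].max()) + 1
        mat = np.full((R, k), np.nan)
        mat[grp["repetition"].to_numpy(), grp["fold"].to_numpy()] = grp[
            "value"
        ].to_numpy(dtype=float)
        if np.any(np.isnan(mat)):
            raise ValueError(f"incomplete score matrix for metric {metric!r} in {path}")
        mats[str(metric)] = mat
    arm_cols = [c for c in df.columns if c not in ("metric", "repetition", "fold", "value")]
    arm = {c: df[c].iloc[0] for c in arm_cols} if arm_cols else {}
    return FoldScoreMatrix(scores=mats, arm=arm)
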