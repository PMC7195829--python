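"""Stratified cross-validation, the four performance metrics, and the
imbalance-ratio experiment.

ECM is the positive class throughout. Metrics:

    Sn  = TP / (TP + FN)            sensitivity (recall on ECM)
    Sp  = TN / (TN + FP)            specificity (recall on nonECM)
    Acc = (TP + TN) / n             overall accuracy
    BAcc = (Sn + Sp) / 2            balanced accuracy, the headline criterion

Cross-validation pools the held-out predictions of all folds and computes one
confusion matrix from the pool (more stable than per-fold averaging when a
fold holds only ~50 positives). Everything that depends on the training data
— including the negative-subset partition of the under-sampling ensemble —
is recomputed inside each training split, so held-out folds never leak into
training.

The imbalance experiment quantifies raw class-imbalance damage: for each
ratio r it keeps all positives, samples r * n_pos negatives without
replacement, and cross-validates a single plain random forest (no ensemble),
averaging metrics over repeated resamplings.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from . import ensemble as ens
from .ensemble import EnsembleConfig
from .io import ECM, NON_ECM


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.tn + self.fp


@dataclasses.dataclass(frozen=True)
class MetricsReport:
    counts: ConfusionCounts
    sn: float
    sp: float
    acc: float
    bacc: float

    def to_frame(self) -> pd.DataFrame:
        c = self.counts
        return pd.DataFrame(
            {
                "TP": [c.tp], "FN": [c.fn], "TN": [c.tn], "FP": [c.fp],
                "Sn": [round(self.sn, 4)], "Sp": [round(self.sp, 4)],
                "Acc": [round(self.acc, 4)], "BAcc": [round(self.bacc, 4)],
            }
        )


@dataclasses.dataclass
class CVResult:
    """Pooled cross-validation outcome with per-sample diagnostics."""

    report: MetricsReport
    probabilities: pd.Series          # held-out mean ECM probability per sample
    fold_ids: np.ndarray
    fold_train_sizes: list[tuple[int, int]]   # (n_pos, n_neg) per training split


def compute_metrics(counts: ConfusionCounts) -> MetricsReport:
    """The four performance metrics from a confusion matrix."""
    if counts.n_pos == 0 or counts.n_neg == 0:
        raise ValueError("metrics undefined: one class is empty")
    sn = counts.tp / counts.n_pos
    sp = counts.tn / counts.n_neg
    acc = (counts.tp + counts.tn) / (counts.n_pos + counts.n_neg)
    bacc = (sn + sp) / 2
    # Acc is the class-size-weighted mean of Sn and Sp; assert the identity.
    assert abs(acc - (counts.n_pos * sn + counts.n_neg * sp) / (counts.n_pos + counts.n_neg)) < 1e-12
    return MetricsReport(counts=counts, sn=sn, sp=sp, acc=acc, bacc=bacc)


def metrics_from_predictions(y_true: Sequence[str], y_pred: Sequence[str]) -> MetricsReport:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    counts = ConfusionCounts(
        tp=int(np.sum((y_true == ECM) & (y_pred == ECM))),
        fn=int(np.sum((y_true == ECM) & (y_pred == NON_ECM))),
        tn=int(np.sum((y_true == NON_ECM) & (y_pred == NON_ECM))),
        fp=int(np.sum((y_true == NON_ECM) & (y_pred == ECM))),
    )
    return compute_metrics(counts)


def stratified_folds(labels: Sequence[str], k: int = 10, seed: int = 0) -> np.ndarray:
    """Fold id (0..k-1) per record; per-class fold counts differ by <= 1."""
    y = np.asarray(labels)
    for cls in np.unique(y):
        if np.sum(y == cls) < k:
            raise ValueError(
                f"class {cls!r} has {np.sum(y == cls)} member(s); "
                f"cannot build {k} stratified folds"
            )
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = np.empty(len(y), dtype=int)
    for fold_id, (_, test_idx) in enumerate(splitter.split(np.zeros(len(y)), y)):
        folds[test_idx] = fold_id
    return folds


def cross_validate(
    features: pd.DataFrame,
    labels: pd.Series,
    config: EnsembleConfig | None = None,
    k: int = 10,
    seed: int = 0,
    folds: np.ndarray | None = None,
) -> CVResult:
    """k-fold CV of the under-sampling ensemble with pooled held-out metrics."""
    config = config or EnsembleConfig()
    y = np.asarray(labels)
    if folds is None:
        folds = stratified_folds(y, k=k, seed=seed)
    probs = np.full(len(y), np.nan)
    train_sizes = []
    for fold_id in np.unique(folds):
        train_mask = folds != fold_id
        model = ens.train_ensemble(
            features.iloc[train_mask], y[train_mask], config=config
        )
        train_sizes.append((model.n_pos, model.n_neg))
        probs[~train_mask] = ens.predict_proba(model, features.iloc[~train_mask])
    assert not np.isnan(probs).any()
    y_pred = np.where(probs >= config.decision_threshold, ECM, NON_ECM)
    report = metrics_from_predictions(y, y_pred)
    index = labels.index if isinstance(labels, pd.Series) else pd.RangeIndex(len(y))
    return CVResult(
        report=report,
        probabilities=pd.Series(probs, index=index, name="probability"),
        fold_ids=folds,
        fold_train_sizes=train_sizes,
    )


def single_forest_cv(
    features: pd.DataFrame,
    labels: pd.Series,
    n_trees: int = 500,
    k: int = 10,
    seed: int = 0,
    decision_threshold: float = 0.5,
) -> MetricsReport:
    """k-fold CV of one plain random forest trained on the full (imbalanced) split."""
    y = np.asarray(labels)
    X = features.to_numpy(dtype=float)
    folds = stratified_folds(y, k=k, seed=seed)
    probs = np.full(len(y), np.nan)
    for fold_id in np.unique(folds):
        train = folds != fold_id
        forest = RandomForestClassifier(
            n_estimators=n_trees,
            random_state=ens.learner_seed(seed, int(fold_id)),
            n_jobs=1,
        )
        forest.fit(X[train], (y[train] == ECM).astype(int))
        ecm_col = int(np.flatnonzero(forest.classes_ == 1)[0])
        probs[~train] = forest.predict_proba(X[~train])[:, ecm_col]
    y_pred = np.where(probs >= decision_threshold, ECM, NON_ECM)
    return metrics_from_predictions(y, y_pred)


def imbalance_experiment(
    features: pd.DataFrame,
    labels: pd.Series,
    ratios: Sequence[int] = tuple(range(1, 22)),
    repeats: int = 10,
    seed: int = 0,
    k: int = 10,
    n_trees: int = 500,
) -> pd.DataFrame:
    """Mean single-forest CV metrics at negative:positive ratios 1..R.

    Each repeat redraws the negative subsample without replacement; metrics
    are averaged over repeats per ratio.
    """
    y = np.asarray(labels)
    pos_idx = np.flatnonzero(y == ECM)
    neg_idx = np.flatnonzero(y == NON_ECM)
    n_pos = len(pos_idx)
    if len(neg_idx) < max(ratios) * n_pos:
        raise ValueError(
            f"need at least {max(ratios) * n_pos} negatives for ratio "
            f"1:{max(ratios)}, have {len(neg_idx)}"
        )
    rng = np.random.default_rng(seed)
    rows = []
    for ratio in ratios:
        metrics = np.zeros(4)
        for rep in range(repeats):
            chosen_neg = rng.choice(neg_idx, size=ratio * n_pos, replace=False)
            rows_idx = np.concatenate([pos_idx, chosen_neg])
            rep_seed = ens.learner_seed(seed, ratio * 1000 + rep)
            report = single_forest_cv(
                features.iloc[rows_idx],
                pd.Series(y[rows_idx]),
                n_trees=n_trees,
                k=k,
                seed=rep_seed,
            )
            metrics += np.array([report.sn, report.sp, report.acc, report.bacc])
        metrics /= repeats
        rows.append(
            {"ratio": ratio, "Sn": metrics[0], "Sp": metrics[1],
             "Acc": metrics[2], "BAcc": metrics[3]}
        )
    return pd.DataFrame(rows)
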