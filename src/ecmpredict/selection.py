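"""mRMR feature ranking and incremental feature selection (IFS).

Features are first discretized: binary 0/1 columns pass through unchanged,
continuous columns are three-binned at mean +/- one standard deviation into
codes {-1, 0, +1}. Relevance and redundancy are plug-in mutual information
(base 2) over the empirical joints. Ranking is greedy mutual-information
difference (MID): the first feature maximizes I(f; class), each subsequent
pick maximizes I(f; class) - mean_{s in S} I(f; s) over the already-ranked
set S. Ties are broken by input column order.

IFS then evaluates the nested top-k subsets of the ranking with one shared
cross-validation fold partition, so the curve isolates the effect of k from
fold noise, and the optimal subset size is the smallest k attaining the
maximum balanced accuracy.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import mutual_info_score

from . import evaluation
from .ensemble import EnsembleConfig


def discretize_feature(values: Sequence[float]) -> np.ndarray:
    """Three-bin a continuous feature at mean +/- sigma; keep binary features."""
    v = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("cannot discretize non-finite values")
    uniq = np.unique(v)
    if set(uniq.tolist()) <= {0.0, 1.0}:
        return v.astype(np.int64)
    mu, sigma = v.mean(), v.std()
    codes = np.zeros(v.shape, dtype=np.int64)
    codes[v < mu - sigma] = -1
    codes[v > mu + sigma] = 1
    return codes


def discretize_matrix(features: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame(
        {name: discretize_feature(features[name].to_numpy()) for name in features.columns},
        index=features.index,
    )


def mutual_information(x: Sequence, y: Sequence) -> float:
    """Plug-in mutual information of two discrete vectors, in bits."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    return float(mutual_info_score(y, x) / math.log(2))


def mrmr_rank(codes: pd.DataFrame, labels: Sequence) -> pd.DataFrame:
    """Greedy MID ranking of all feature columns.

    Returns a frame with columns ``feature``, ``score`` (the greedy objective
    at selection time, in bits) and ``rank`` (1-based).
    """
    if codes.shape[1] < 1:
        raise ValueError("need at least one feature column")
    y = np.asarray(labels)
    names = list(codes.columns)
    X = {name: codes[name].to_numpy() for name in names}
    relevance = {name: mutual_information(X[name], y) for name in names}

    selected: list[str] = []
    scores: list[float] = []
    redundancy_sum = {name: 0.0 for name in names}
    remaining = list(names)
    while remaining:
        best_name, best_score = None, -np.inf
        for name in remaining:  # input order; strict > keeps earlier column on ties
            if selected:
                score = relevance[name] - redundancy_sum[name] / len(selected)
            else:
                score = relevance[name]
            if score > best_score:
                best_name, best_score = name, score
        selected.append(best_name)
        scores.append(best_score)
        remaining.remove(best_name)
        for name in remaining:
            redundancy_sum[name] += mutual_information(X[name], X[best_name])
    return pd.DataFrame(
        {"feature": selected, "score": scores, "rank": np.arange(1, len(selected) + 1)}
    )


def ifs_evaluate(
    features: pd.DataFrame,
    labels: pd.Series,
    ranking: pd.DataFrame,
    config: EnsembleConfig | None = None,
    k_folds: int = 10,
    seed: int = 0,
    max_k: int | None = None,
) -> pd.DataFrame:
    """Cross-validate every nested top-k subset of the ranking.

    All subset sizes share one stratified fold partition derived from
    ``seed``, so rows of the returned curve differ only in the feature set.
    """
    config = config or EnsembleConfig()
    ordered = list(ranking["feature"])
    missing = set(ordered) - set(features.columns)
    if missing:
        raise ValueError(f"ranking names unknown feature(s): {sorted(missing)[:5]}")
    folds = evaluation.stratified_folds(labels, k=k_folds, seed=seed)
    n = len(ordered) if max_k is None else min(max_k, len(ordered))
    rows = []
    for k in range(1, n + 1):
        subset = ordered[:k]
        result = evaluation.cross_validate(
            features[subset], labels, config=config, k=k_folds, seed=seed, folds=folds
        )
        m = result.report
        rows.append({"k": k, "Sn": m.sn, "Sp": m.sp, "Acc": m.acc, "BAcc": m.bacc})
    return pd.DataFrame(rows)


def select_optimal(curve: pd.DataFrame) -> int:
    """Smallest subset size attaining the maximum balanced accuracy."""
    if curve.empty:
        raise ValueError("empty IFS curve")
    best = int(curve.loc[curve["BAcc"].idxmax(), "k"])  # idxmax -> first maximum
    return best
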