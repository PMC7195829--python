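"""Under-sampling ensemble of random forests for imbalanced ECM prediction.

The negative class outnumbers the positive class roughly 21:1 in curated
training data. Rather than discarding negatives, the negatives are shuffled
and split into K = floor(n_neg / n_pos) disjoint, near-equal subsets; base
learner j is a random forest trained on all positives plus negative subset j.
Every negative therefore contributes to exactly one learner, so the ensemble
uses the full sample while each learner sees a balanced problem. Predicted
ECM probabilities are the unweighted mean over the K learners (soft voting),
which yields the continuous probability the confidence threshold is applied
to.

Thresholds: a protein is labeled ECM when its mean probability is at least
the decision threshold (default 0.5); it is flagged high-confidence when the
probability strictly exceeds the confidence threshold (default 0.7).
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .io import ECM, NON_ECM


@dataclasses.dataclass
class EnsembleConfig:
    """Training configuration for the under-sampling ensemble."""

    n_trees: int = 500
    mtry: int | str = "sqrt"
    k: int | str = "auto"
    seed: int = 0
    feature_subset: tuple[str, ...] | None = None
    decision_threshold: float = 0.5
    confidence_threshold: float = 0.7

    def __post_init__(self) -> None:
        if not (0.0 < self.decision_threshold < 1.0):
            raise ValueError("decision_threshold must lie in (0, 1)")
        if self.k != "auto" and int(self.k) < 1:
            raise ValueError("k must be >= 1 or 'auto'")


def learner_seed(seed: int, j: int) -> int:
    """Deterministic per-learner seed fan-out via numpy's SeedSequence."""
    return int(np.random.SeedSequence([seed, j]).generate_state(1)[0] % (2**31))


def partition_negatives(n_neg: int, n_pos: int, seed: int, k: int | str = "auto") -> list[np.ndarray]:
    """Shuffle 0..n_neg-1 and split into K disjoint near-equal subsets.

    K defaults to floor(n_neg / n_pos) so each subset is roughly the size of
    the positive class. Subset sizes differ by at most one (the leftover
    negatives are spread one per subset), and the union covers all negatives.
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("need at least one sample in each class")
    if k == "auto":
        if n_neg < n_pos:
            warnings.warn(
                "fewer negatives than positives; falling back to a single "
                "(unbalanced) base learner",
                stacklevel=2,
            )
            k = 1
        else:
            k = n_neg // n_pos
    k = int(k)
    perm = np.random.default_rng(seed).permutation(n_neg)
    return [np.sort(chunk) for chunk in np.array_split(perm, k)]


@dataclasses.dataclass
class UnderSamplingEnsemble:
    """K trained random forests over disjoint balanced resamples."""

    learners: list[RandomForestClassifier]
    feature_names: tuple[str, ...]
    config: EnsembleConfig
    n_pos: int
    n_neg: int
    partition_sizes: tuple[int, ...]

    @property
    def k(self) -> int:
        return len(self.learners)

    def _validate_features(self, features: pd.DataFrame) -> np.ndarray:
        missing = set(self.feature_names) - set(features.columns)
        if missing:
            raise ValueError(f"input lacks model feature(s): {sorted(missing)[:5]}")
        extra = set(features.columns) - set(self.feature_names)
        if extra:
            raise ValueError(
                f"input carries {len(extra)} feature(s) unknown to the model, "
                f"e.g. {sorted(extra)[:3]}"
            )
        return features[list(self.feature_names)].to_numpy(dtype=float)


def train_ensemble(
    features: pd.DataFrame,
    labels: Sequence[str],
    config: EnsembleConfig | None = None,
) -> UnderSamplingEnsemble:
    """Fit K balanced random forests on (all positives, negative subset j)."""
    config = config or EnsembleConfig()
    y = np.asarray(labels)
    if config.feature_subset is not None:
        features = features[list(config.feature_subset)]
    X = features.to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("feature matrix contains non-finite values")
    pos_idx = np.flatnonzero(y == ECM)
    neg_idx = np.flatnonzero(y == NON_ECM)
    if len(pos_idx) == 0 or len(neg_idx) == 0:
        raise ValueError("training data must contain both ECM and nonECM samples")

    subsets = partition_negatives(len(neg_idx), len(pos_idx), seed=config.seed, k=config.k)
    learners = []
    for j, subset in enumerate(subsets):
        rows = np.concatenate([pos_idx, neg_idx[subset]])
        forest = RandomForestClassifier(
            n_estimators=config.n_trees,
            max_features=config.mtry,
            random_state=learner_seed(config.seed, j),
            n_jobs=1,
        )
        forest.fit(X[rows], (y[rows] == ECM).astype(int))
        learners.append(forest)
    return UnderSamplingEnsemble(
        learners=learners,
        feature_names=tuple(features.columns),
        config=config,
        n_pos=len(pos_idx),
        n_neg=len(neg_idx),
        partition_sizes=tuple(len(s) for s in subsets),
    )


def predict_proba(model: UnderSamplingEnsemble, features: pd.DataFrame) -> np.ndarray:
    """Mean ECM-class probability over the K base learners."""
    X = model._validate_features(features)
    probs = np.zeros(len(X))
    for forest in model.learners:
        ecm_col = int(np.flatnonzero(forest.classes_ == 1)[0])
        probs += forest.predict_proba(X)[:, ecm_col]
    return probs / model.k


def classify(
    probabilities: Sequence[float],
    protein_ids: Sequence[str],
    decision_threshold: float = 0.5,
    confidence_threshold: float = 0.7,
) -> pd.DataFrame:
    """Threshold mean probabilities into labels and confidence flags.

    The ECM label uses ``p >= decision_threshold``; the high-confidence flag
    is strict (``p > confidence_threshold``), so a probability of exactly 0.7
    is labeled ECM but not flagged confident under the defaults.
    """
    p = np.asarray(probabilities, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    return pd.DataFrame(
        {
            "protein_id": list(protein_ids),
            "probability": p,
            "label": np.where(p >= decision_threshold, ECM, NON_ECM),
            "high_confidence": p > confidence_threshold,
        }
    )
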