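import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import RandomForestClassifier

import ecmpredict.ensemble as ens
import ecmpredict.io as eio
from ecmpredict.io import ECM, NON_ECM


# ---------------------------------------------------------------------------
# Negative partition

def test_partition_at_curated_dataset_scale():
    # 11,336 negatives against 521 positives -> 21 near-equal subsets
    subsets = ens.partition_negatives(11336, 521, seed=0)
    assert len(subsets) == 21
    assert set(len(s) for s in subsets) == {539, 540}


def test_partition_exact_and_degenerate_cases():
    assert [len(s) for s in ens.partition_negatives(30, 10, seed=1)] == [10, 10, 10]
    assert len(ens.partition_negatives(10, 10, seed=1)) == 1
    with pytest.warns(UserWarning, match="fewer negatives"):
        subsets = ens.partition_negatives(5, 10, seed=1)
    assert len(subsets) == 1


def test_partition_is_true_partition_random_pairs():
    rng = np.random.default_rng(0)
    for _ in range(100):
        n_pos = int(rng.integers(1, 60))
        n_neg = int(rng.integers(n_pos, 40 * n_pos))
        subsets = ens.partition_negatives(n_neg, n_pos, seed=int(rng.integers(1 << 30)))
        sizes = [len(s) for s in subsets]
        assert len(subsets) == n_neg // n_pos
        assert max(sizes) - min(sizes) <= 1
        merged = np.concatenate(subsets)
        assert len(merged) == n_neg and len(np.unique(merged)) == n_neg


# ---------------------------------------------------------------------------
# Training and prediction

def _imbalanced_problem(seed=0, n_pos=12, n_neg=48, p=8):
    rng = np.random.default_rng(seed)
    y = np.array([ECM] * n_pos + [NON_ECM] * n_neg)
    X = rng.normal(size=(n_pos + n_neg, p))
    X[:n_pos, 0] += 3.0  # separable signal
    return pd.DataFrame(X, columns=[f"f{i}" for i in range(p)]), y


def test_training_set_separable_gives_perfect_recall():
    X, y = _imbalanced_problem()
    model = ens.train_ensemble(X, y, ens.EnsembleConfig(n_trees=50, seed=0))
    assert model.k == 4
    probs = ens.predict_proba(model, X)
    assert ((probs >= 0.5) == (y == ECM)).all()


def test_same_seed_identical_predictions():
    X, y = _imbalanced_problem(seed=3)
    config = ens.EnsembleConfig(n_trees=30, seed=9)
    p1 = ens.predict_proba(ens.train_ensemble(X, y, config), X)
    p2 = ens.predict_proba(ens.train_ensemble(X, y, config), X)
    assert (p1 == p2).all()


def test_k1_balanced_reduces_to_single_forest():
    X, y = _imbalanced_problem(seed=5, n_pos=20, n_neg=20)
    config = ens.EnsembleConfig(n_trees=40, seed=2)
    model = ens.train_ensemble(X, y, config)
    assert model.k == 1
    direct = RandomForestClassifier(
        n_estimators=40, max_features="sqrt",
        random_state=ens.learner_seed(2, 0), n_jobs=1,
    )
    pos = np.flatnonzero(y == ECM)
    neg = np.flatnonzero(y == NON_ECM)
    rows = np.concatenate([pos, neg])
    direct.fit(X.to_numpy()[rows], (y[rows] == ECM).astype(int))
    want = direct.predict_proba(X.to_numpy())[:, 1]
    assert ens.predict_proba(model, X) == pytest.approx(want)


def test_predict_proba_is_mean_of_learners():
    X, y = _imbalanced_problem(seed=7)
    model = ens.train_ensemble(X, y, ens.EnsembleConfig(n_trees=30, seed=1))
    per_learner = np.stack(
        [f.predict_proba(X.to_numpy())[:, list(f.classes_).index(1)]
         for f in model.learners]
    )
    assert ens.predict_proba(model, X) == pytest.approx(per_learner.mean(axis=0))
    assert (ens.predict_proba(model, X) <= per_learner.max(axis=0) + 1e-12).all()
    assert (ens.predict_proba(model, X) >= per_learner.min(axis=0) - 1e-12).all()


def test_single_class_input_rejected():
    X, y = _imbalanced_problem()
    with pytest.raises(ValueError, match="both"):
        ens.train_ensemble(X, np.array([ECM] * len(y)))


# ---------------------------------------------------------------------------
# Thresholding

def test_classify_thresholds_exact_and_strict():
    result = ens.classify([0.70, 0.49, 0.71, 1.0], ["a", "b", "c", "d"])
    assert result["label"].tolist() == [ECM, NON_ECM, ECM, ECM]
    # the confidence flag is strictly greater-than 0.7
    assert result["high_confidence"].tolist() == [False, False, True, True]
    # under default thresholds high confidence implies the ECM label
    assert (result.loc[result["high_confidence"], "label"] == ECM).all()


def test_classify_rejects_out_of_range():
    with pytest.raises(ValueError, match="0, 1"):
        ens.classify([1.2], ["a"])


# ---------------------------------------------------------------------------
# Persistence

def test_model_roundtrip_bitwise(tmp_path):
    X, y = _imbalanced_problem(seed=11, p=5)
    model = ens.train_ensemble(X, y, ens.EnsembleConfig(n_trees=25, seed=4))
    path = tmp_path / "model.joblib"
    eio.save_model(model, path)
    loaded = eio.load_model(path)
    assert (ens.predict_proba(loaded, X) == ens.predict_proba(model, X)).all()
    assert loaded.feature_names == model.feature_names
    assert loaded.config.seed == 4


def test_model_load_rejects_corrupt_and_wrong_version(tmp_path):
    path = tmp_path / "bad.joblib"
    path.write_text("not a model")
    with pytest.raises(eio.FormatError):
        eio.load_model(path)
    import joblib
    joblib.dump({"format_version": 999, "model": None}, path)
    with pytest.raises(eio.FormatError, match="version"):
        eio.load_model(path)


def test_reloaded_model_rejects_wrong_feature_set(tmp_path):
    X, y = _imbalanced_problem(seed=13, p=5)
    model = ens.train_ensemble(X, y, ens.EnsembleConfig(n_trees=25, seed=4))
    path = tmp_path / "model.joblib"
    eio.save_model(model, path)
    loaded = eio.load_model(path)
    wider = X.copy()
    wider["f_extra"] = 0.0
    with pytest.raises(ValueError, match="unknown to the model"):
        ens.predict_proba(loaded, wider)
    with pytest.raises(ValueError, match="lacks"):
        ens.predict_proba(loaded, X.drop(columns=["f0"]))
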