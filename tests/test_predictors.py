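"""Correlation ranking, cosine kNN, CV learning curves, splits, ROC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from agingaccel import predictors as pred
from agingaccel import synthetic as syn

from conftest import make_matrix


# ---------------------------------------------------------------------------
# ranking
# ---------------------------------------------------------------------------

def test_rank_genes_examples():
    matrix = make_matrix(
        [[0, 0, 1, 1],      # identical to labels -> r = 1
         [1, 2, 3, 4],      # r = 2 / sqrt(5)
         [5, 5, 5, 5]],     # constant -> r = 0, last
        genes=["g_label", "g_linear", "g_const"],
    )
    ranked = pred.rank_genes_by_correlation(matrix, [0, 0, 1, 1])
    assert list(ranked["gene"]) == ["g_label", "g_linear", "g_const"]
    assert ranked["r"].iloc[0] == pytest.approx(1.0)
    assert ranked["r"].iloc[1] == pytest.approx(0.8944, abs=1e-4)
    assert ranked["r"].iloc[2] == 0.0
    assert list(ranked["rank"]) == [1, 2, 3]


def test_rank_genes_single_class_errors():
    matrix = make_matrix([[1, 2, 3]])
    with pytest.raises(ValueError, match="both label values"):
        pred.rank_genes_by_correlation(matrix, [1, 1, 1])


@given(a=st.floats(0.1, 10), b=st.floats(-5, 5))
@settings(max_examples=25, deadline=None, derandomize=True)
def test_ranking_invariant_to_positive_affine_transform(a, b):
    rng = np.random.default_rng(0)
    matrix = make_matrix(rng.normal(size=(6, 12)))
    labels = rng.integers(0, 2, size=12)
    labels[:2], labels[-2:] = 0, 1
    base = pred.rank_genes_by_correlation(matrix, labels)
    scaled = pred.rank_genes_by_correlation(matrix * a + b, labels)
    assert list(base["gene"]) == list(scaled["gene"])
    assert np.allclose(base["r"], scaled["r"], atol=1e-10)


# ---------------------------------------------------------------------------
# kNN
# ---------------------------------------------------------------------------

def _model(train_values, labels, k, genes=None):
    train = make_matrix(train_values, genes=genes,
                        samples=[f"T{i}" for i in range(np.shape(train_values)[1])])
    return pred.KnnModel(list(train.index), k, train, np.asarray(labels))


def test_knn_enumerated_cosine_example():
    """1-D values lifted to 2-D with a constant; all distances enumerable by hand.

    Cosine similarities of (2.5, 1) with (1,1), (2,1), (3,1), (10,1) are
    0.9192, 0.9965, 0.9983, 0.9608, so the 3 nearest are samples 2, 3, 4
    (labels 0, 1, 1) -> vote 1 with score 2/3.
    """
    model = _model([[1, 2, 3, 10], [1, 1, 1, 1]], [0, 0, 1, 1], k=3)
    query = make_matrix([[2.5], [1.0]], genes=list(model.train_matrix.index), samples=["q"])
    labels, scores = pred.knn_predict(model, query)
    assert labels[0] == 1
    assert scores[0] == pytest.approx(2 / 3)
    # full distance enumeration against the implementation
    q = np.array([2.5, 1.0])
    expected = [1 - (q @ t) / (np.linalg.norm(q) * np.linalg.norm(t))
                for t in ([1, 1], [2, 1], [3, 1], [10, 1])]
    dist = pred._cosine_distance(q[None, :], model.train_matrix.to_numpy().T)
    assert np.allclose(dist[0], expected, atol=1e-12)


def test_knn_unanimous_training_labels():
    model = _model([[1, 2, 3, 4]], [1, 1, 1, 1], k=3)
    query = make_matrix([[2.2, 9.0]], genes=list(model.train_matrix.index))
    labels, scores = pred.knn_predict(model, query)
    assert labels.tolist() == [1, 1] and scores.tolist() == [1.0, 1.0]


def test_knn_query_equal_to_training_sample_k1():
    model = _model([[1, 5], [2, 1]], [0, 1], k=1)
    query = make_matrix([[5], [1]], genes=list(model.train_matrix.index), samples=["q"])
    labels, scores = pred.knn_predict(model, query)
    assert labels[0] == 1 and scores[0] == 1.0


def test_knn_invariant_to_positive_sample_rescaling():
    rng = np.random.default_rng(3)
    model = _model(rng.normal(size=(4, 10)), rng.integers(0, 2, 10), k=5)
    q = rng.normal(size=(4, 6))
    base = pred.knn_predict(model, make_matrix(q, genes=list(model.train_matrix.index)))
    scaled = pred.knn_predict(
        model, make_matrix(q * rng.uniform(0.1, 7, size=6), genes=list(model.train_matrix.index))
    )
    assert np.array_equal(base[0], scaled[0])
    assert np.allclose(base[1], scaled[1])


def test_knn_zero_norm_query_uses_orthogonal_convention():
    model = _model([[1, -1], [1, -1]], [0, 1], k=2)
    query = make_matrix([[0.0], [0.0]], genes=list(model.train_matrix.index), samples=["q"])
    labels, scores = pred.knn_predict(model, query)
    # both training points at distance 1 -> tie in votes -> class 0
    assert labels[0] == 0 and scores[0] == 0.5


# ---------------------------------------------------------------------------
# CV learning curve
# ---------------------------------------------------------------------------

def test_cv_perfectly_separable_genes_reach_accuracy_one():
    """Two antagonistic planted genes (g1 ~ y, g2 ~ 1-y) put the two classes at
    orthogonal directions, which cosine kNN separates perfectly.  (A single
    gene cannot: cosine distance ignores the magnitude of a 1-D vector.)"""
    rng = np.random.default_rng(5)
    y = np.array([0, 1] * 30)
    g1 = y + rng.normal(0, 0.01, size=60)
    g2 = (1 - y) + rng.normal(0, 0.01, size=60)
    matrix = make_matrix(np.vstack([g1, g2, rng.normal(size=(8, 60))]))
    curve = pred.cross_validate_feature_counts(matrix, y, max_features=10, seed=0)
    assert curve.selected_accuracy == 1.0
    assert curve.selected_n == 2


def test_cv_null_labels_stay_in_chance_band():
    rng = np.random.default_rng(6)
    matrix = make_matrix(rng.normal(size=(50, 200)))
    y = np.array([0] * 100 + [1] * 100)
    curve = pred.cross_validate_feature_counts(matrix, y, max_features=50, seed=1)
    assert 0.35 <= curve.selected_accuracy <= 0.65


def test_cv_deterministic_under_seed_and_caps_features():
    rng = np.random.default_rng(7)
    matrix = make_matrix(rng.normal(size=(8, 60)))
    y = rng.integers(0, 2, 60)
    y[:10], y[-10:] = 0, 1
    with pytest.warns(UserWarning, match="capped"):
        c1 = pred.cross_validate_feature_counts(matrix, y, max_features=20, seed=3)
    with pytest.warns(UserWarning, match="capped"):
        c2 = pred.cross_validate_feature_counts(matrix, y, max_features=20, seed=3)
    assert c1.selected_n == c2.selected_n
    assert np.array_equal(c1.mean_accuracy, c2.mean_accuracy)
    assert len(c1.feature_counts) == 8


def test_cv_matches_naive_per_fold_reimplementation():
    """Oracle: recompute one fold's accuracies with plain loops."""
    rng = np.random.default_rng(8)
    matrix = make_matrix(rng.normal(size=(6, 40)))
    y = np.array([0, 1] * 20)
    folds, k = 4, 3
    curve = pred.cross_validate_feature_counts(matrix, y, max_features=6,
                                               folds=folds, k=k, seed=2)
    from sklearn.model_selection import StratifiedKFold

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=2)
    accs = []
    for tr, va in skf.split(np.zeros(len(y)), y):
        ranked = pred.rank_genes_by_correlation(matrix.iloc[:, tr], y[tr])
        per_n = []
        for n in range(1, 7):
            feats = ranked["gene"].head(n).tolist()
            model = pred.KnnModel(feats, k, matrix.loc[feats].iloc[:, tr], y[tr])
            labels, _ = pred.knn_predict(model, matrix.iloc[:, va])
            per_n.append((labels == y[va]).mean())
        accs.append(per_n)
    assert np.allclose(curve.mean_accuracy, np.mean(accs, axis=0), atol=1e-12)


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------

def test_split_is_stratified_two_to_one_and_deterministic():
    labels = pd.Series([0] * 300 + [1] * 285,
                       index=[f"S{i}" for i in range(585)])
    train, test = pred.split_train_test(labels, seed=4)
    assert sorted(train + test) == sorted(labels.index)
    for cls in (0, 1):
        n_cls = (labels == cls).sum()
        n_test = sum(labels[t] == cls for t in test)
        assert abs(n_test - n_cls / 3) <= 1
    assert pred.split_train_test(labels, seed=4) == (train, test)
    assert pred.split_train_test(labels, seed=5) != (train, test)


def test_split_single_class_and_tiny_class_error():
    with pytest.raises(ValueError, match="both classes"):
        pred.split_train_test(pd.Series([1, 1, 1], index=list("abc")), seed=0)
    with pytest.raises(ValueError, match="fewer than 3"):
        pred.split_train_test(pd.Series([0, 0, 0, 1, 1], index=list("abcde")), seed=0)


# ---------------------------------------------------------------------------
# evaluation / ROC
# ---------------------------------------------------------------------------

def test_auc_brute_force_concordance_oracle(rng):
    """AUC (trapezoid over the ROC step curve) equals the concordance fraction."""
    from sklearn.metrics import auc as trap_auc, roc_curve

    for _ in range(20):
        n = 30
        scores = rng.choice(np.linspace(0, 1, 11), size=n)  # ties included
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            continue
        fpr, tpr, _ = roc_curve(labels, scores)
        auc = trap_auc(fpr, tpr)
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
        assert auc == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-12)


def test_evaluate_model_known_auc_values():
    train = make_matrix([[1, 2, 3, 4, 5, 6], [1, 1, 1, 1, 1, 1]])
    model = pred.KnnModel(list(train.index), 1, train, np.array([0, 0, 0, 1, 1, 1]))
    test = make_matrix([[1.1, 2.1, 4.9, 5.9], [1, 1, 1, 1]], genes=list(train.index))
    result = pred.evaluate_model(model, test, [0, 0, 1, 1])
    assert result.accuracy == 1.0 and result.auc == 1.0
    # degenerate: constant scores -> diagonal ROC
    from sklearn.metrics import auc as trap_auc, roc_curve
    fpr, tpr, _ = roc_curve([1, 0, 1, 0], [0.5, 0.5, 0.5, 0.5])
    assert trap_auc(fpr, tpr) == 0.5
    # hand example via concordance: scores [.9,.8,.4,.2], labels [1,0,1,0] -> 0.75
    fpr, tpr, _ = roc_curve([1, 0, 1, 0], [0.9, 0.8, 0.4, 0.2])
    assert trap_auc(fpr, tpr) == pytest.approx(0.75)


def test_no_leakage_test_data_does_not_affect_model():
    """Corrupting held-out expression must leave the trained model untouched."""
    cfg = syn.SyntheticConfig(n_genes=40, n_young=30, n_old_normal=30, n_pd=0,
                              n_aging_genes=5, seed=17)
    matrix, table, _ = syn.generate_cohort(cfg)
    r1 = pred.train_aging_predictor(matrix, table, seed=9, max_features=10)
    corrupted = matrix.copy()
    rng = np.random.default_rng(0)
    corrupted[r1.test_ids] = rng.normal(size=(matrix.shape[0], len(r1.test_ids)))
    r2 = pred.train_aging_predictor(corrupted, table, seed=9, max_features=10)
    assert r2.train_ids == r1.train_ids and r2.test_ids == r1.test_ids
    assert r1.model.feature_genes == r2.model.feature_genes
    assert np.array_equal(r1.curve.mean_accuracy, r2.curve.mean_accuracy)
    assert not np.array_equal(r1.roc.scores, r2.roc.scores)  # test outputs do change


def test_improved_beats_traditional_on_masked_construction():
    from agingaccel import evaluation as ev

    pairs = ev.paired_predictor_comparison(n_seeds=2, base_seed=3)
    for improved, traditional in pairs:
        assert improved > traditional


def test_zero_pd_effect_keeps_both_predictors_at_chance():
    cfg = syn.SyntheticConfig(n_genes=60, n_young=60, n_old_normal=60, n_pd=60,
                              n_aging_genes=0, aging_effect=0.0, n_pd_genes=0,
                              pd_effect=0.0, n_diff_edges=0, masking_latent_sd=0.0,
                              platform_shift_sd=0.0, seed=23)
    matrix, table, _ = syn.generate_cohort(cfg)
    improved = pred.train_improved_pd_predictor(matrix, table, seed=1, max_features=30)
    traditional = pred.train_traditional_pd_predictor(matrix, table, seed=1, max_features=30)
    for result in (improved, traditional):
        assert 0.3 <= result.curve.selected_accuracy <= 0.7
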