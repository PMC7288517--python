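"""Correlation-ranked cosine-kNN predictors.

Three classifiers share one recipe: rank genes by the absolute Pearson
correlation of their expression with a binary phenotype (young=0/old=1 or
normal=0/PD=1), build kNN models (k = 5, cosine distance) on the top-n genes
for n = 1..100, select n by mean 10-fold cross-validated accuracy, and
evaluate the selected model on a held-out third of the samples.

* aging predictor: young vs old normal samples;
* improved PD predictor: old-normal vs PD after residualizing on the top-3
  young principal directions;
* traditional PD predictor: the same comparison on the original data.

By default the gene ranking is recomputed inside each CV training fold so the
learning curve is leakage-free; ``rank_once=True`` ranks a single time on the
whole training set (the simpler, slightly optimistic variant).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve
from sklearn.model_selection import StratifiedKFold

from .preprocess import residualize_on_young

logger = logging.getLogger(__name__)

DEFAULT_K = 5
DEFAULT_FOLDS = 10
DEFAULT_MAX_FEATURES = 100


# ---------------------------------------------------------------------------
# gene ranking
# ---------------------------------------------------------------------------

def rank_genes_by_correlation(matrix: pd.DataFrame, labels) -> pd.DataFrame:
    """Rank genes by |Pearson r| against binary labels coded {0, 1}.

    Returns a DataFrame (gene, r, rank) sorted by |r| descending, ties broken
    lexicographically by gene id; zero-variance genes get r = 0.
    """
    y = np.asarray(labels, dtype=float)
    if y.shape[0] != matrix.shape[1]:
        raise ValueError("labels must align with matrix columns")
    if y.shape[0] < 3:
        raise ValueError("at least 3 samples required")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("both label values must be present")
    X = matrix.to_numpy(dtype=float)
    r = _pearson_with_vector(X, y)
    order = np.lexsort((np.asarray(matrix.index), -np.abs(r)))
    ranked = pd.DataFrame(
        {
            "gene": np.asarray(matrix.index)[order],
            "r": r[order],
            "rank": np.arange(1, len(r) + 1),
        }
    )
    return ranked


def _pearson_with_vector(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation of X (genes x samples) with y."""
    yc = y - y.mean()
    sy = np.sqrt((yc ** 2).sum())
    Xc = X - X.mean(axis=1, keepdims=True)
    sx = np.sqrt((Xc ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc @ yc) / (sx * sy)
    r[~np.isfinite(r)] = 0.0
    return np.clip(r, -1.0, 1.0)


# ---------------------------------------------------------------------------
# kNN with cosine distance
# ---------------------------------------------------------------------------

@dataclass
class KnnModel:
    """kNN classifier over a fixed ordered feature-gene panel."""

    feature_genes: list[str]
    k: int
    train_matrix: pd.DataFrame  # genes (= feature_genes) x training samples
    train_labels: np.ndarray

    def __post_init__(self) -> None:
        self.train_labels = np.asarray(self.train_labels, dtype=int)
        n_train = self.train_matrix.shape[1]
        if not 1 <= self.k <= n_train:
            raise ValueError(f"k must be in [1, {n_train}], got {self.k}")
        if list(self.train_matrix.index) != list(self.feature_genes):
            raise ValueError("training matrix rows must equal feature_genes in order")


def _cosine_distance(queries: np.ndarray, train: np.ndarray) -> np.ndarray:
    """1 - cosine similarity between query rows and training rows.

    Zero-norm vectors use the orthogonal convention (similarity 0, distance 1).
    """
    qn = np.linalg.norm(queries, axis=1)
    tn = np.linalg.norm(train, axis=1)
    if (qn == 0).any() or (tn == 0).any():
        logger.warning("zero-norm feature vector(s); cosine distance set to 1")
    denom = np.outer(qn, tn)
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = (queries @ train.T) / denom
    sim[~np.isfinite(sim)] = 0.0
    return 1.0 - sim


def knn_predict(model: KnnModel, queries: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Predict labels and class-1 vote fractions for query samples.

    ``queries`` is genes x samples and must contain every feature gene.
    Neighbour ties at equal distance resolve in training-sample index order;
    an even vote split predicts class 0.
    """
    missing = [g for g in model.feature_genes if g not in queries.index]
    if missing:
        raise KeyError(f"queries missing feature genes: {missing}")
    Q = queries.loc[model.feature_genes].to_numpy(dtype=float).T
    T = model.train_matrix.to_numpy(dtype=float).T
    dist = _cosine_distance(Q, T)
    neighbours = np.argsort(dist, axis=1, kind="stable")[:, : model.k]
    votes = model.train_labels[neighbours]
    score = votes.mean(axis=1)
    return (score > 0.5).astype(int), score


# ---------------------------------------------------------------------------
# cross-validated learning curve
# ---------------------------------------------------------------------------

@dataclass
class CvCurve:
    """Mean CV accuracy per candidate feature count; selected_n maximizes it."""

    feature_counts: np.ndarray
    mean_accuracy: np.ndarray
    selected_n: int
    fold_accuracy: np.ndarray = field(default=None, repr=False)

    @property
    def selected_accuracy(self) -> float:
        return float(self.mean_accuracy[self.selected_n - 1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"n_features": self.feature_counts, "mean_cv_accuracy": self.mean_accuracy}
        )


def _vote_accuracy_curves(
    Xtr: np.ndarray, ytr: np.ndarray, Xva: np.ndarray, yva: np.ndarray, k: int
) -> np.ndarray:
    """Validation accuracy of top-n cosine-kNN for every n = 1..F at once.

    X arrays are samples x F with columns already in rank order.  Uses
    cumulative dot products / squared norms over the feature axis so the F
    models share one pass.
    """
    F = Xtr.shape[1]
    prod = Xva[:, None, :] * Xtr[None, :, :]
    cumdot = np.cumsum(prod, axis=2)
    # norms via sqrt-then-product so the arithmetic matches knn_predict exactly
    # (a sqrt-of-products denominator can differ by 1 ulp and flip distance ties)
    norm_tr = np.sqrt(np.cumsum(Xtr ** 2, axis=1))
    norm_va = np.sqrt(np.cumsum(Xva ** 2, axis=1))
    acc = np.empty(F)
    for n in range(1, F + 1):
        denom = np.outer(norm_va[:, n - 1], norm_tr[:, n - 1])
        with np.errstate(invalid="ignore", divide="ignore"):
            sim = cumdot[:, :, n - 1] / denom
        sim[~np.isfinite(sim)] = 0.0
        dist = 1.0 - sim
        neighbours = np.argsort(dist, axis=1, kind="stable")[:, :k]
        pred = (ytr[neighbours].mean(axis=1) > 0.5).astype(int)
        acc[n - 1] = (pred == yva).mean()
    return acc


def cross_validate_feature_counts(
    matrix: pd.DataFrame,
    labels,
    max_features: int = DEFAULT_MAX_FEATURES,
    folds: int = DEFAULT_FOLDS,
    k: int = DEFAULT_K,
    seed: int = 0,
    rank_once: bool = False,
) -> CvCurve:
    """Stratified k-fold learning curve over candidate feature counts.

    For each fold, genes are ranked on the training portion only (unless
    ``rank_once``), and the top-n kNN model is evaluated on the held-out fold
    for every n.  ``selected_n`` is the smallest n attaining the maximal mean
    accuracy.
    """
    y = np.asarray(labels, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("binary labels required")
    if counts.min() < folds:
        raise ValueError(
            f"each class needs >= {folds} samples for {folds}-fold CV, got {counts.min()}"
        )
    if max_features > matrix.shape[0]:
        warnings.warn(
            f"max_features {max_features} exceeds available genes {matrix.shape[0]}; capped",
            stacklevel=2,
        )
        max_features = matrix.shape[0]
    global_rank = rank_genes_by_correlation(matrix, y) if rank_once else None
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    X = matrix.to_numpy(dtype=float)
    fold_acc = []
    for tr_idx, va_idx in skf.split(np.zeros(len(y)), y):
        if rank_once:
            ranked_genes = global_rank["gene"].to_numpy()
        else:
            fold_rank = rank_genes_by_correlation(matrix.iloc[:, tr_idx], y[tr_idx])
            ranked_genes = fold_rank["gene"].to_numpy()
        top = ranked_genes[:max_features]
        pos = matrix.index.get_indexer(top)
        Xtr = X[np.ix_(pos, tr_idx)].T
        Xva = X[np.ix_(pos, va_idx)].T
        fold_acc.append(_vote_accuracy_curves(Xtr, y[tr_idx], Xva, y[va_idx], k))
    fold_acc = np.asarray(fold_acc)
    mean_acc = fold_acc.mean(axis=0)
    selected_n = int(np.argmax(mean_acc)) + 1  # argmax returns first max -> smallest n
    return CvCurve(
        feature_counts=np.arange(1, max_features + 1),
        mean_accuracy=mean_acc,
        selected_n=selected_n,
        fold_accuracy=fold_acc,
    )


# ---------------------------------------------------------------------------
# train/test split and evaluation
# ---------------------------------------------------------------------------

def split_train_test(
    labels: pd.Series, seed: int, test_fraction: float = 1.0 / 3.0
) -> tuple[list, list]:
    """Stratified ~2:1 split; deterministic under seed.

    ``labels`` is indexed by sample id.  Every stratum needs >= 3 samples so
    both partitions are populated.
    """
    rng = np.random.default_rng(seed)
    classes = labels.unique()
    if len(classes) < 2:
        raise ValueError("both classes must be present to split")
    train, test = [], []
    for cls in sorted(map(str, classes)):
        ids = sorted(labels.index[labels.astype(str) == cls])
        if len(ids) < 3:
            raise ValueError(f"class {cls!r} has fewer than 3 samples")
        ids = list(rng.permutation(ids))
        n_test = max(1, int(round(len(ids) * test_fraction)))
        test.extend(ids[:n_test])
        train.extend(ids[n_test:])
    return sorted(train), sorted(test)


@dataclass
class RocResult:
    """Majority-vote accuracy plus ROC over vote-fraction scores."""

    scores: np.ndarray
    labels: np.ndarray
    accuracy: float
    auc: float  # NaN when the test set has a single class
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"fpr": self.fpr, "tpr": self.tpr, "threshold": self.thresholds})


def evaluate_model(model: KnnModel, test_matrix: pd.DataFrame, test_labels) -> RocResult:
    """Accuracy (majority vote) and trapezoid AUC from vote-fraction scores."""
    y = np.asarray(test_labels, dtype=int)
    if y.size == 0:
        raise ValueError("test set is empty")
    pred, score = knn_predict(model, test_matrix)
    accuracy = float((pred == y).mean())
    if len(np.unique(y)) < 2:
        return RocResult(score, y, accuracy, float("nan"),
                         np.array([]), np.array([]), np.array([]))
    fpr, tpr, thr = _roc_curve(y, score)
    return RocResult(score, y, accuracy, float(_trapezoid_auc(fpr, tpr)), fpr, tpr, thr)


# ---------------------------------------------------------------------------
# full predictor pipelines
# ---------------------------------------------------------------------------

@dataclass
class PredictorResult:
    """Bundle of one trained predictor: model, ranking, learning curve, test ROC."""

    task: str
    model: KnnModel
    ranking: pd.DataFrame
    curve: CvCurve
    roc: RocResult
    train_ids: list
    test_ids: list

    @property
    def marker_genes(self) -> list[str]:
        return list(self.model.feature_genes)


def _train_binary(
    matrix: pd.DataFrame,
    labels: pd.Series,
    task: str,
    seed: int,
    *,
    k: int = DEFAULT_K,
    folds: int = DEFAULT_FOLDS,
    max_features: int = DEFAULT_MAX_FEATURES,
    rank_once: bool = False,
) -> PredictorResult:
    train_ids, test_ids = split_train_test(labels, seed)
    X_train = matrix[train_ids]
    y_train = labels.loc[train_ids].to_numpy(dtype=int)
    curve = cross_validate_feature_counts(
        X_train, y_train, max_features=max_features, folds=folds, k=k,
        seed=seed, rank_once=rank_once,
    )
    ranking = rank_genes_by_correlation(X_train, y_train)
    features = ranking["gene"].head(curve.selected_n).tolist()
    model = KnnModel(features, k, X_train.loc[features], y_train)
    roc = evaluate_model(model, matrix[test_ids], labels.loc[test_ids].to_numpy(dtype=int))
    return PredictorResult(task, model, ranking, curve, roc, train_ids, test_ids)


def train_aging_predictor(
    matrix: pd.DataFrame, table: pd.DataFrame, seed: int, age_cutoff: float = 50, **kwargs
) -> PredictorResult:
    """Young (<cutoff, label 0) vs old (label 1) classifier on normal samples."""
    meta = table.set_index("sample_id")
    normal = [c for c in matrix.columns if meta.loc[c, "group"] == "normal"]
    labels = pd.Series(
        [(1 if meta.loc[c, "age"] >= age_cutoff else 0) for c in normal], index=normal
    )
    return _train_binary(matrix[normal], labels, "aging", seed, **kwargs)


def _pd_labels(table: pd.DataFrame, columns, age_cutoff: float) -> pd.Series:
    meta = table.set_index("sample_id")
    eligible = [
        c for c in columns
        if meta.loc[c, "group"] == "PD" or meta.loc[c, "age"] >= age_cutoff
    ]
    return pd.Series(
        [(1 if meta.loc[c, "group"] == "PD" else 0) for c in eligible], index=eligible
    )


def train_improved_pd_predictor(
    matrix: pd.DataFrame, table: pd.DataFrame, seed: int, age_cutoff: float = 50, **kwargs
) -> PredictorResult:
    """Old-normal (0) vs PD (1) on young-residualized expression."""
    meta = table.set_index("sample_id")
    young = [
        c for c in matrix.columns
        if meta.loc[c, "group"] == "normal" and meta.loc[c, "age"] < age_cutoff
    ]
    if not young:
        raise ValueError("no young normal samples available for residualization")
    labels = _pd_labels(table, matrix.columns, age_cutoff)
    old_pd = [c for c in labels.index if c not in set(young)]
    resid = residualize_on_young(matrix[old_pd], matrix[young])
    return _train_binary(resid, labels.loc[old_pd], "pd-improved", seed, **kwargs)


def train_traditional_pd_predictor(
    matrix: pd.DataFrame, table: pd.DataFrame, seed: int, age_cutoff: float = 50, **kwargs
) -> PredictorResult:
    """Old-normal (0) vs PD (1) on the original expression (no residualization)."""
    meta = table.set_index("sample_id")
    labels = _pd_labels(table, matrix.columns, age_cutoff)
    old_pd = [
        c for c in labels.index
        if not (meta.loc[c, "group"] == "normal" and meta.loc[c, "age"] < age_cutoff)
    ]
    return _train_binary(matrix[old_pd], labels.loc[old_pd], "pd-traditional", seed, **kwargs)
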