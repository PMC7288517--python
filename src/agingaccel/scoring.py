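"""Transcriptomic aging scores.

The aging score of a sample is the prediction of its sigmoid-transformed
chronological age from a no-intercept linear regression on the expression of
the aging markers:

    t(age) = 1 / (1 + exp(-(age - center) / scale))        (center = scale = 50)
    score  = sum_i b_i * marker_i

Accelerated aging in disease is then assessed by comparing score distributions
between PD and control samples within cumulative age groups (age >= 50, 55, ...,
85) with the Kruskal-Wallis rank test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_AGE_CENTER = 50.0
DEFAULT_AGE_SCALE = 50.0
DEFAULT_THRESHOLDS = (50, 55, 60, 65, 70, 75, 80, 85)


def sigmoid_age(age, center: float = DEFAULT_AGE_CENTER, scale: float = DEFAULT_AGE_SCALE):
    """Map chronological age (years) to a dimensionless value in (0, 1).

    Strictly increasing; equals 0.5 at ``center``.  Accepts scalars or arrays.
    """
    age = np.asarray(age, dtype=float)
    out = 1.0 / (1.0 + np.exp(-(age - center) / scale))
    return float(out) if out.ndim == 0 else out


@dataclass
class AgingScoreModel:
    """No-intercept linear model mapping marker expression to transformed age."""

    marker_ids: list[str]
    coefficients: np.ndarray
    intercept: float = 0.0
    fitted: bool = True

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.coefficients) != len(self.marker_ids):
            raise ValueError("one coefficient per marker required")
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("coefficients must be finite")


def fit_aging_score(
    matrix: pd.DataFrame,
    ages: pd.Series | Sequence[float],
    *,
    transformed: bool = False,
    add_intercept: bool = False,
    center: float = DEFAULT_AGE_CENTER,
    scale: float = DEFAULT_AGE_SCALE,
) -> AgingScoreModel:
    """Least-squares fit of (sigmoid-transformed) age on marker expression.

    ``matrix`` is genes x samples, restricted to the aging markers; every row
    is used as a marker.  With fewer samples than markers the minimum-norm
    solution is returned with a warning.  ``transformed=True`` means ``ages``
    are already on the (0, 1) transformed scale.
    """
    if matrix.isna().any().any():
        raise ValueError("marker matrix contains missing values")
    ages = np.asarray(ages, dtype=float)
    if ages.shape[0] != matrix.shape[1]:
        raise ValueError("ages must align with matrix columns")
    y = ages if transformed else sigmoid_age(ages, center, scale)
    X = matrix.to_numpy(dtype=float).T  # samples x markers
    if add_intercept:
        X = np.column_stack([np.ones(X.shape[0]), X])
    if X.shape[0] <= X.shape[1]:
        warnings.warn(
            "fewer samples than markers: minimum-norm least-squares solution",
            stacklevel=2,
        )
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    if add_intercept:
        return AgingScoreModel(list(matrix.index), coef[1:], intercept=float(coef[0]))
    return AgingScoreModel(list(matrix.index), coef)


def score_samples(model: AgingScoreModel, matrix: pd.DataFrame) -> pd.Series:
    """Aging score per sample: b . expression (+ intercept if fitted with one)."""
    if not model.fitted:
        raise ValueError("model is not fitted")
    missing = [m for m in model.marker_ids if m not in matrix.index]
    if missing:
        raise KeyError(f"marker rows missing from matrix: {missing}")
    X = matrix.loc[model.marker_ids].to_numpy(dtype=float)
    scores = model.coefficients @ X + model.intercept
    return pd.Series(scores, index=matrix.columns, name="aging_score")


def kruskal_wallis(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-group Kruskal-Wallis H (tie-corrected) and chi-square (df=1) p-value.

    Identical pooled values (zero rank variance) give H = 0, p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(a, b)
    return float(h), float(p)


@dataclass
class GroupComparison:
    """Per-age-threshold PD-vs-control summary (Table-2-style layout)."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def compare_groups(
    scores: pd.Series,
    table: pd.DataFrame,
    thresholds: Iterable[int] = DEFAULT_THRESHOLDS,
) -> GroupComparison:
    """Compare aging scores of PD vs control within cumulative age groups.

    For each threshold t the comparison uses every sample with age >= t.  Rows
    where either group is empty are marked absent (``present=False``) with NaN
    statistics.
    """
    meta = table.set_index("sample_id") if "sample_id" in table.columns else table
    common = scores.index.intersection(meta.index)
    if len(common) == 0:
        raise ValueError("no overlap between scores and sample table")
    meta = meta.loc[common]
    scores = scores.loc[common]
    rows = []
    for t in thresholds:
        sel = meta["age"] >= t
        pd_mask = sel & (meta["group"] == "PD")
        ctl_mask = sel & (meta["group"] == "normal")
        row = {"age_threshold": t, "n_pd": int(pd_mask.sum()), "n_control": int(ctl_mask.sum())}
        if pd_mask.any() and ctl_mask.any():
            s_pd, s_ctl = scores[pd_mask], scores[ctl_mask]
            a_pd, a_ctl = meta.loc[pd_mask, "age"], meta.loc[ctl_mask, "age"]
            h, p = kruskal_wallis(s_pd, s_ctl)
            row.update(
                present=True,
                median_age_pd=float(a_pd.median()),
                median_age_control=float(a_ctl.median()),
                mean_age_pd=float(a_pd.mean()),
                mean_age_control=float(a_ctl.mean()),
                median_score_pd=float(s_pd.median()),
                median_score_control=float(s_ctl.median()),
                mean_score_pd=float(s_pd.mean()),
                mean_score_control=float(s_ctl.mean()),
                kruskal_h=h,
                p_value=p,
            )
        else:
            row.update(present=False, kruskal_h=np.nan, p_value=np.nan)
        rows.append(row)
    return GroupComparison(pd.DataFrame(rows))
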