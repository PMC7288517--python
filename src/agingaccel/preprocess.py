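"""Probe collapse, gene/sample filtering, and multi-platform normalization.

The normalization emulates the standard recipe for merging case/control
microarray cohorts across platforms, applied independently within each
platform:

1. per-gene z-score using the mean/SD of the normal samples on that platform;
2. removal of the rank-3 SVD reconstruction (top three singular triplets)
   from the normal block and the PD block separately, to strip dominant
   inter-sample variation;
3. per-gene z-score of all samples using the old-normal mean/SD computed
   after step 2, putting every platform on a common old-normal scale.

A separate step, :func:`residualize_on_young`, projects old/PD samples onto
the orthogonal complement of the top-3 principal directions of the healthy
young samples (directions in gene space), so that disease effects hidden
under shared young-sample covariation become visible.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ZERO_FRACTION_CUTOFF = 0.30
AGE_CUTOFF = 50
N_SVD_COMPONENTS = 3


def collapse_probes(probe_matrix: pd.DataFrame, probe_map: Mapping[str, str]) -> pd.DataFrame:
    """Collapse a probes x samples matrix to genes x samples by mean.

    Probes absent from ``probe_map`` are dropped; probes sharing a gene symbol
    are summarized by the arithmetic mean per sample.
    """
    if len(probe_map) == 0:
        raise ValueError("probe map is empty")
    if any(not sym for sym in probe_map.values()):
        raise ValueError("probe map contains empty gene symbols")
    symbols = pd.Series({p: probe_map[p] for p in probe_matrix.index if p in probe_map})
    kept = probe_matrix.loc[symbols.index]
    collapsed = kept.groupby(symbols).mean()
    collapsed.index.name = "GENE_SYMBOL"
    return collapsed.sort_index()


def read_probe_map(path) -> dict[str, str]:
    """Two-column TSV (probe_id, gene_symbol) -> dict."""
    df = pd.read_csv(path, sep="\t", header=None, names=["probe_id", "gene_symbol"], dtype=str)
    df = df.dropna()
    return dict(zip(df["probe_id"], df["gene_symbol"]))


def fill_and_filter_genes(
    matrix: pd.DataFrame, zero_fraction: float = ZERO_FRACTION_CUTOFF
) -> pd.DataFrame:
    """Fill missing values with 0, then drop genes with >= 30% exact zeros."""
    filled = matrix.fillna(0.0)
    frac_zero = (filled == 0).mean(axis=1)
    kept = filled.loc[frac_zero < zero_fraction]
    if kept.shape[0] == 0:
        raise ValueError("empty matrix after filtering")
    return kept


def filter_samples(
    matrix: pd.DataFrame, table: pd.DataFrame, age_cutoff: float = AGE_CUTOFF
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove early-onset PD samples (PD with age < cutoff); normals untouched."""
    missing = [s for s in matrix.columns if s not in set(table["sample_id"])]
    if missing:
        raise ValueError(f"sample table does not cover matrix samples: {missing}")
    drop = table[(table["group"] == "PD") & (table["age"] < age_cutoff)]["sample_id"]
    drop_set = set(drop)
    kept_table = table[~table["sample_id"].isin(drop_set)].reset_index(drop=True)
    kept_matrix = matrix.drop(columns=[c for c in matrix.columns if c in drop_set])
    return kept_matrix, kept_table


def _safe_zscore(block: np.ndarray, mu: np.ndarray, sd: np.ndarray, what: str) -> np.ndarray:
    """Per-gene z-score; zero-SD genes map to 0 with a warning."""
    degenerate = sd == 0
    if degenerate.any():
        logger.warning(
            "%d zero-variance gene(s) in %s reference; z-scores set to 0", degenerate.sum(), what
        )
    sd = np.where(degenerate, 1.0, sd)
    z = (block - mu[:, None]) / sd[:, None]
    z[degenerate, :] = 0.0
    return z


def _remove_rank_k(block: np.ndarray, k: int = N_SVD_COMPONENTS) -> np.ndarray:
    """Subtract the rank-k truncated SVD reconstruction of the block."""
    if min(block.shape) == 0:
        return block
    u, s, vt = np.linalg.svd(block, full_matrices=False)
    k = min(k, len(s))
    return block - (u[:, :k] * s[:k]) @ vt[:k]


def normalize_platform(matrix: pd.DataFrame, table: pd.DataFrame) -> pd.DataFrame:
    """Three-step normalization, applied independently within each platform.

    Requires each platform to have at least one normal and one old-normal
    sample; SVD removal on a block with fewer than 4 samples is skipped with
    a warning (too few samples to separate structure from noise).
    """
    meta = table.set_index("sample_id")
    out = matrix.copy().astype(float)
    for platform, ids in meta.groupby("platform").groups.items():
        cols = [c for c in matrix.columns if c in set(ids)]
        if not cols:
            continue
        sub = meta.loc[cols]
        normal_cols = [c for c in cols if sub.loc[c, "group"] == "normal"]
        pd_cols = [c for c in cols if sub.loc[c, "group"] == "PD"]
        old_normal_cols = [
            c for c in normal_cols if sub.loc[c, "age"] >= AGE_CUTOFF
        ]
        if not normal_cols:
            raise ValueError(f"platform {platform!r} has no normal samples")
        if not old_normal_cols:
            raise ValueError(f"platform {platform!r} has no old-normal samples")
        block = out[cols].to_numpy()
        col_pos = {c: i for i, c in enumerate(cols)}

        # step 1: z-score on normal-sample statistics
        ref = block[:, [col_pos[c] for c in normal_cols]]
        block = _safe_zscore(block, ref.mean(axis=1), ref.std(axis=1, ddof=0),
                             f"platform {platform} normal samples")

        # step 2: rank-3 SVD removal, normal and PD blocks separately
        for group_cols in (normal_cols, pd_cols):
            if len(group_cols) == 0:
                continue
            idx = [col_pos[c] for c in group_cols]
            if len(idx) < 4:
                logger.warning(
                    "platform %s: block of %d sample(s) too small for SVD removal; skipped",
                    platform, len(idx),
                )
                continue
            block[:, idx] = _remove_rank_k(block[:, idx])

        # step 3: z-score all samples on post-SVD old-normal statistics
        ref = block[:, [col_pos[c] for c in old_normal_cols]]
        block = _safe_zscore(block, ref.mean(axis=1), ref.std(axis=1, ddof=0),
                             f"platform {platform} old-normal samples")
        out.loc[:, cols] = block
    return out


def young_principal_directions(matrix_young: pd.DataFrame, k: int = 3):
    """Top-k principal directions (gene space) of the young block.

    Returns (gene_means, directions) where directions is an orthonormal
    (k x genes) array of right singular vectors of the young-mean-centered
    samples x genes matrix.  Fewer than k nonzero singular values reduce the
    number of directions with a warning.
    """
    Y = matrix_young.to_numpy(dtype=float).T  # samples x genes
    if Y.shape[0] < 4:
        raise ValueError("young matrix must have at least 4 samples")
    mean = Y.mean(axis=0)
    Yc = Y - mean
    _, s, vt = np.linalg.svd(Yc, full_matrices=False)
    tol = max(Yc.shape) * np.finfo(float).eps * (s[0] if len(s) else 0.0)
    nonzero = int((s > tol).sum())
    if nonzero < k:
        logger.warning(
            "young block has only %d nonzero singular values; using %d direction(s)",
            nonzero, nonzero,
        )
    return mean, vt[: min(k, nonzero)]


def residualize_on_young(
    matrix_old_pd: pd.DataFrame, matrix_young: pd.DataFrame, k: int = 3
) -> pd.DataFrame:
    """Residualize old/PD samples on the top-k young principal directions.

    Both matrices are genes x samples; they are intersected on genes (error if
    the intersection is empty).  Each old/PD sample vector is centered on the
    young gene means and its least-squares projection onto the young principal
    directions is removed; with orthonormal directions this is the orthogonal
    projection onto their complement.
    """
    shared = matrix_old_pd.index.intersection(matrix_young.index)
    if len(shared) == 0:
        raise ValueError("old/PD and young matrices share no genes")
    X = matrix_old_pd.loc[shared]
    mean, directions = young_principal_directions(matrix_young.loc[shared], k=k)
    Xc = X.to_numpy(dtype=float).T - mean  # samples x genes
    if directions.shape[0] > 0:
        coef = Xc @ directions.T          # OLS coefficients (orthonormal basis)
        Xc = Xc - coef @ directions
    return pd.DataFrame(Xc.T, index=shared, columns=X.columns)
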