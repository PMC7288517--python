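"""Aging-acceleration network from differential (partial) correlations.

For every unordered gene pair the Pearson correlation is computed separately
in control (old-normal) and PD samples, together with the first-order partial
correlation given the aging score:

    rp_xy.z = (r_xy - r_xz * r_yz) / sqrt((1 - r_xz^2) (1 - r_yz^2))

An edge joins a pair when (a) at least one of its four coefficients is
significant under Benjamini-Hochberg FDR < 0.05 (configurable: any / all /
off), and (b) both |r_control - r_pd| and |rp_control - rp_pd| exceed 0.5
(strictly).  Networks built on independent sample splits are compared with
Fisher's exact test over the pair universe, and the degree distribution is
checked for the scale-free signature (negative log-degree / log-frequency
correlation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

DELTA_THRESHOLD = 0.5
FDR_THRESHOLD = 0.05


# ---------------------------------------------------------------------------
# correlation primitives
# ---------------------------------------------------------------------------

def _corr_pvalues(r: np.ndarray, n: int, df: int) -> np.ndarray:
    """Two-sided p from the t statistic t = r sqrt(df / (1 - r^2))."""
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    return np.clip(p, 0.0, 1.0)


def pairwise_correlation(matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs Pearson r and two-sided p (df = n - 2) for genes x samples.

    Zero-variance genes get r = 0 and p = 1 off-diagonal (diagonal r = 1).
    """
    n = matrix.shape[1]
    if n < 4:
        raise ValueError(f"at least 4 samples required, got {n}")
    X = matrix.to_numpy(dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    norm = np.sqrt((Xc ** 2).sum(axis=1))
    degenerate = norm == 0
    norm_safe = np.where(degenerate, 1.0, norm)
    Z = Xc / norm_safe[:, None]
    R = np.clip(Z @ Z.T, -1.0, 1.0)
    R[degenerate, :] = 0.0
    R[:, degenerate] = 0.0
    P = _corr_pvalues(R, n, n - 2)
    P[degenerate, :] = 1.0
    P[:, degenerate] = 1.0
    np.fill_diagonal(R, 1.0)
    np.fill_diagonal(P, 0.0)
    idx = matrix.index
    return pd.DataFrame(R, index=idx, columns=idx), pd.DataFrame(P, index=idx, columns=idx)


def partial_correlation(x, y, z) -> tuple[float, float]:
    """First-order partial correlation of x and y given the covariate z.

    p-value from a t statistic with df = n - 3.  If either variable is
    perfectly correlated with z the coefficient is undefined; the convention
    rp = 0, p = 1 is used with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    n = x.size
    if not (y.size == n and z.size == n):
        raise ValueError("x, y, z must have equal length")
    if n < 5:
        raise ValueError("at least 5 samples required")
    r_xy = _scalar_corr(x, y)
    r_xz = _scalar_corr(x, z)
    r_yz = _scalar_corr(y, z)
    denom_sq = (1.0 - r_xz ** 2) * (1.0 - r_yz ** 2)
    if denom_sq <= 0.0:
        logger.warning("degenerate covariate (|r with z| = 1); partial correlation set to 0")
        return 0.0, 1.0
    rp = float(np.clip((r_xy - r_xz * r_yz) / np.sqrt(denom_sq), -1.0, 1.0))
    p = float(_corr_pvalues(np.array(rp), n, n - 3))
    return rp, p


def _scalar_corr(a: np.ndarray, b: np.ndarray) -> float:
    ac = a - a.mean()
    bc = b - b.mean()
    na, nb = np.linalg.norm(ac), np.linalg.norm(bc)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.clip(ac @ bc / (na * nb), -1.0, 1.0))


def partial_correlation_matrix(
    matrix: pd.DataFrame, covariate
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs first-order partial correlation given one covariate vector."""
    n = matrix.shape[1]
    if n < 5:
        raise ValueError(f"at least 5 samples required, got {n}")
    R, _ = pairwise_correlation(matrix)
    z = np.asarray(covariate, dtype=float)
    X = matrix.to_numpy(dtype=float)
    r_z = _pearson_rows(X, z)
    denom_sq = np.outer(1.0 - r_z ** 2, 1.0 - r_z ** 2)
    degenerate = np.abs(r_z) >= 1.0
    if degenerate.any():
        logger.warning(
            "%d gene(s) perfectly correlated with the covariate; partial r set to 0",
            degenerate.sum(),
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        RP = (R.to_numpy() - np.outer(r_z, r_z)) / np.sqrt(denom_sq)
    RP = np.clip(RP, -1.0, 1.0)
    RP[degenerate, :] = 0.0
    RP[:, degenerate] = 0.0
    PP = _corr_pvalues(RP, n, n - 3)
    PP[degenerate, :] = 1.0
    PP[:, degenerate] = 1.0
    np.fill_diagonal(RP, 1.0)
    np.fill_diagonal(PP, 0.0)
    idx = matrix.index
    return pd.DataFrame(RP, index=idx, columns=idx), pd.DataFrame(PP, index=idx, columns=idx)


def _pearson_rows(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    yc = y - y.mean()
    sy = np.linalg.norm(yc)
    Xc = X - X.mean(axis=1, keepdims=True)
    sx = np.linalg.norm(Xc, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc @ yc) / (sx * sy)
    r[~np.isfinite(r)] = 0.0
    return np.clip(r, -1.0, 1.0)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, clipped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------

@dataclass
class DifferentialNetwork:
    """Retained differential-correlation edges over a gene universe."""

    graph: nx.Graph
    edges: pd.DataFrame
    universe: list[str]
    params: dict = field(default_factory=dict)

    @property
    def edge_set(self) -> set[frozenset]:
        return {frozenset((a, b)) for a, b in self.graph.edges()}

    def to_tsv(self, path) -> None:
        self.edges.to_csv(path, sep="\t", index=False)


def build_network(
    control_matrix: pd.DataFrame,
    pd_matrix: pd.DataFrame,
    control_scores,
    pd_scores,
    delta_threshold: float = DELTA_THRESHOLD,
    fdr_threshold: float = FDR_THRESHOLD,
    significance_mode: str = "any",
    max_genes: int = 2000,
) -> DifferentialNetwork:
    """Build the aging-acceleration network between control and PD samples.

    Edge retained iff the FDR gate passes (min/max of the four coefficient
    q-values below ``fdr_threshold`` under mode any/all; mode "off" disables
    the gate) AND both absolute coefficient differences strictly exceed
    ``delta_threshold``.
    """
    if significance_mode not in ("any", "all", "off"):
        raise ValueError(f"significance_mode must be any|all|off, got {significance_mode!r}")
    shared = control_matrix.index.intersection(pd_matrix.index)
    if len(shared) == 0:
        raise ValueError("control and PD matrices share no genes")
    if len(shared) > max_genes:
        raise ValueError(
            f"{len(shared)} genes exceed the configured cap of {max_genes}; "
            "all-pairs analysis at this scale must be requested explicitly"
        )
    ctl = control_matrix.loc[shared]
    pdm = pd_matrix.loc[shared]
    Rc, Pc = pairwise_correlation(ctl)
    Rd, Pd_ = pairwise_correlation(pdm)
    RPc, PPc = partial_correlation_matrix(ctl, control_scores)
    RPd, PPd = partial_correlation_matrix(pdm, pd_scores)

    iu = np.triu_indices(len(shared), k=1)
    fam_p = [m.to_numpy()[iu] if isinstance(m, pd.DataFrame) else m[iu]
             for m in (Pc, Pd_, PPc, PPd)]
    fam_q = np.vstack([bh_fdr(p) for p in fam_p])
    q_min = fam_q.min(axis=0)
    q_max = fam_q.max(axis=0)
    if significance_mode == "any":
        gate = q_min < fdr_threshold
    elif significance_mode == "all":
        gate = q_max < fdr_threshold
    else:
        gate = np.ones_like(q_min, dtype=bool)

    rc, rd = Rc.to_numpy()[iu], Rd.to_numpy()[iu]
    rpc, rpd = RPc.to_numpy()[iu], RPd.to_numpy()[iu]
    delta_r = np.abs(rc - rd)
    delta_rp = np.abs(rpc - rpd)
    retained = gate & (delta_r > delta_threshold) & (delta_rp > delta_threshold)

    genes = np.asarray(shared)
    rows = pd.DataFrame(
        {
            "gene_a": genes[iu[0]][retained],
            "gene_b": genes[iu[1]][retained],
            "r_control": rc[retained],
            "r_pd": rd[retained],
            "rp_control": rpc[retained],
            "rp_pd": rpd[retained],
            "delta_r": delta_r[retained],
            "delta_rp": delta_rp[retained],
            "q_min": q_min[retained],
        }
    )
    graph = nx.Graph()
    for row in rows.itertuples(index=False):
        graph.add_edge(row.gene_a, row.gene_b, delta_r=row.delta_r, delta_rp=row.delta_rp)
    params = {
        "delta_threshold": delta_threshold,
        "fdr_threshold": fdr_threshold,
        "significance_mode": significance_mode,
        "n_control": int(ctl.shape[1]),
        "n_pd": int(pdm.shape[1]),
    }
    return DifferentialNetwork(graph=graph, edges=rows, universe=list(shared), params=params)


def network_similarity_fisher(
    netA: DifferentialNetwork, netB: DifferentialNetwork
) -> tuple[float, float]:
    """Two-sided Fisher's exact test of edge overlap over the shared pair universe."""
    universe = sorted(set(netA.universe) & set(netB.universe))
    if len(universe) < 2:
        raise ValueError("empty common gene universe")
    total_pairs = len(universe) * (len(universe) - 1) // 2
    uni = set(universe)
    edges_a = {e for e in netA.edge_set if e <= uni}
    edges_b = {e for e in netB.edge_set if e <= uni}
    a = len(edges_a & edges_b)
    b = len(edges_a - edges_b)
    c = len(edges_b - edges_a)
    d = total_pairs - a - b - c
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(odds), float(p)


def scale_free_check(
    network: DifferentialNetwork | nx.Graph, min_degree: int = 1
) -> tuple[float, float]:
    """Pearson r of log10(degree) vs log10(frequency) over the degree distribution.

    Returns (nan, nan) when fewer than 3 distinct degrees are observed.
    """
    graph = network.graph if isinstance(network, DifferentialNetwork) else network
    degrees = np.array([d for _, d in graph.degree() if d >= min_degree])
    if degrees.size == 0:
        return float("nan"), float("nan")
    values, counts = np.unique(degrees, return_counts=True)
    if len(values) < 3:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(np.log10(values), np.log10(counts))
    return float(r), float(p)
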