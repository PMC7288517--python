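"""Aging-PD marker pairs on the aging-acceleration network.

For every (aging marker, PD marker) pair connected in the (unweighted)
network one deterministic shortest path is computed: breadth-first distance
from the PD end plus a greedy walk that always steps to the smallest-labelled
neighbour one level closer, which yields the lexicographically smallest
shortest node sequence.  Pairs whose control/PD correlation coefficients have
strictly opposite signs are retained; per-marker linkage scores sum |r_control
- r_pd| over retained pairs.  Path betweenness counts, for each gene, the
retained-pair shortest paths in which it appears as an interior node, and a
permutation test re-draws random marker sets of the same sizes to judge
whether the observed betweenness exceeds chance.
"""

from __future__ import annotations

import logging
from collections import Counter, deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .network import DifferentialNetwork

logger = logging.getLogger(__name__)

DEFAULT_PERMUTATIONS = 1000


@dataclass
class MarkerPair:
    """One aging-PD marker pair with its (optional) shortest path."""

    aging_marker: str
    pd_marker: str
    path: list[str] | None = None
    r_control: float = float("nan")
    r_pd: float = float("nan")
    is_max_diff: bool = False

    @property
    def diff(self) -> float:
        return self.r_control - self.r_pd

    @property
    def abs_diff(self) -> float:
        return abs(self.diff)

    @property
    def opposite_sign(self) -> bool:
        return self.r_control * self.r_pd < 0

    @property
    def path_length(self) -> int | None:
        return None if self.path is None else len(self.path) - 1


def _adjacency(graph: nx.Graph) -> dict[str, list[str]]:
    return {node: sorted(graph.neighbors(node)) for node in graph.nodes}


def _bfs_distances(adj: Mapping[str, list[str]], source: str) -> dict[str, int]:
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def _lex_shortest_path(
    adj: Mapping[str, list[str]], dist_to_target: Mapping[str, int], start: str
) -> list[str]:
    """Greedy walk down the BFS distance field; neighbours tried in sorted order.

    Choosing the smallest feasible next node at every step yields the
    lexicographically smallest node sequence among all shortest paths.
    """
    path = [start]
    current = start
    while dist_to_target[current] > 0:
        level = dist_to_target[current] - 1
        current = next(v for v in adj[current] if dist_to_target.get(v, -1) == level)
        path.append(current)
    return path


def shortest_paths(
    network: DifferentialNetwork | nx.Graph,
    aging_markers: Sequence[str],
    pd_markers: Sequence[str],
) -> list[MarkerPair]:
    """One MarkerPair per (aging, PD) candidate; unconnected pairs have no path.

    Markers absent from the network are logged and yield path-less pairs; the
    two marker sets must be role-disjoint.
    """
    graph = network.graph if isinstance(network, DifferentialNetwork) else network
    overlap = set(aging_markers) & set(pd_markers)
    if overlap:
        raise ValueError(f"genes cannot be both aging and PD markers: {sorted(overlap)}")
    adj = _adjacency(graph)
    absent = [m for m in [*aging_markers, *pd_markers] if m not in adj]
    if absent:
        logger.info("%d marker(s) absent from the network: %s", len(absent), absent[:10])
    pairs: list[MarkerPair] = []
    dist_cache: dict[str, dict[str, int]] = {}
    for p in pd_markers:
        if p in adj:
            dist_cache[p] = _bfs_distances(adj, p)
    for a in aging_markers:
        for p in pd_markers:
            path = None
            dist = dist_cache.get(p)
            if dist is not None and a in dist:
                path = _lex_shortest_path(adj, dist, a)
            pairs.append(MarkerPair(a, p, path))
    return pairs


def annotate_pair_correlations(
    pairs: Iterable[MarkerPair], r_control: pd.DataFrame, r_pd: pd.DataFrame
) -> list[MarkerPair]:
    """Fill r_control / r_pd for each pair from full correlation matrices."""
    out = []
    for pair in pairs:
        pair.r_control = float(r_control.loc[pair.aging_marker, pair.pd_marker])
        pair.r_pd = float(r_pd.loc[pair.aging_marker, pair.pd_marker])
        out.append(pair)
    return out


def retain_opposite_sign_pairs(
    pairs: Iterable[MarkerPair],
    r_control: pd.DataFrame | None = None,
    r_pd: pd.DataFrame | None = None,
) -> list[MarkerPair]:
    """Keep pairs whose two correlations have strictly opposite signs.

    A zero coefficient (product 0) is not strictly opposite and is dropped.
    The maximum-|diff| retained pair(s) are flagged ``is_max_diff``.
    """
    pairs = list(pairs)
    if r_control is not None and r_pd is not None:
        pairs = annotate_pair_correlations(pairs, r_control, r_pd)
    retained = [p for p in pairs if p.opposite_sign]
    if retained:
        best = max(p.abs_diff for p in retained)
        for p in retained:
            p.is_max_diff = p.abs_diff == best
    return retained


def marker_linkage_scores(
    retained: Sequence[MarkerPair],
) -> tuple[pd.Series, pd.Series, list[str], list[str]]:
    """Per-marker sums of |r_control - r_pd| over retained pairs.

    Returns (aging sums, PD sums, argmax aging markers, argmax PD markers);
    ties in the argmax are all reported, sorted lexicographically.
    """
    aging_sum: Counter = Counter()
    pd_sum: Counter = Counter()
    for p in retained:
        aging_sum[p.aging_marker] += p.abs_diff
        pd_sum[p.pd_marker] += p.abs_diff
    aging = pd.Series(dict(aging_sum), dtype=float).sort_values(ascending=False)
    pdm = pd.Series(dict(pd_sum), dtype=float).sort_values(ascending=False)

    def _argmax(series: pd.Series) -> list[str]:
        if series.empty:
            return []
        return sorted(series.index[series == series.max()])

    return aging, pdm, _argmax(aging), _argmax(pdm)


@dataclass
class BetweennessTable:
    """Gene -> count of retained-pair shortest paths through it (interior only)."""

    table: pd.DataFrame  # columns: gene, betweenness; sorted descending, ties lexicographic

    def top(self, n: int) -> pd.DataFrame:
        return self.table.head(n)

    def lookup(self) -> dict[str, int]:
        return dict(zip(self.table["gene"], self.table["betweenness"]))


def path_betweenness(pairs: Iterable[MarkerPair]) -> BetweennessTable:
    """Count interior-node appearances of each gene across pair paths."""
    counts: Counter = Counter()
    for pair in pairs:
        if pair.path is not None:
            for gene in pair.path[1:-1]:
                counts[gene] += 1
    table = pd.DataFrame(
        sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["gene", "betweenness"],
    )
    return BetweennessTable(table)


def _betweenness_for_genes(
    adj: Mapping[str, list[str]],
    aging: Sequence[str],
    pd_markers: Sequence[str],
    genes: set[str],
) -> Counter:
    """Interior-node path counts restricted to ``genes`` (permutation inner loop)."""
    counts: Counter = Counter()
    for p in pd_markers:
        dist = _bfs_distances(adj, p)
        for a in aging:
            if a not in dist or a == p:
                continue
            path = _lex_shortest_path(adj, dist, a)
            for gene in path[1:-1]:
                if gene in genes:
                    counts[gene] += 1
    return counts


@dataclass
class PermutationResult:
    """Permutation p-values for the observed top-betweenness genes."""

    reps: int
    seed: int
    observed: dict[str, int]
    exceed_counts: dict[str, int]
    p_values: dict[str, float] = field(default_factory=dict)
    smoothed: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": list(self.observed),
                "betweenness": [self.observed[g] for g in self.observed],
                "perm_p": [self.p_values[g] for g in self.observed],
            }
        )


def permutation_test(
    network: DifferentialNetwork | nx.Graph,
    n_aging: int,
    n_pd: int,
    observed: Mapping[str, int],
    reps: int = DEFAULT_PERMUTATIONS,
    seed: int = 0,
    smoothed: bool = False,
) -> PermutationResult:
    """Null distribution of betweenness under random marker sets.

    Each rep draws disjoint random aging/PD node sets of the observed sizes
    from the network nodes, recomputes the deterministic shortest paths, and
    counts how often each observed gene's permuted betweenness reaches its
    observed value; p = count / reps (optionally (count+1)/(reps+1)).
    """
    graph = network.graph if isinstance(network, DifferentialNetwork) else network
    nodes = sorted(graph.nodes)
    if len(nodes) < n_aging + n_pd:
        raise ValueError(
            f"network has {len(nodes)} nodes, fewer than n_aging + n_pd = {n_aging + n_pd}"
        )
    if reps < 1:
        raise ValueError("reps must be >= 1")
    adj = _adjacency(graph)
    genes = set(observed)
    rng = np.random.default_rng(seed)
    exceed = {g: 0 for g in observed}
    node_arr = np.asarray(nodes, dtype=object)
    for _ in range(reps):
        pick = rng.choice(len(nodes), size=n_aging + n_pd, replace=False)
        aging = node_arr[pick[:n_aging]].tolist()
        pdm = node_arr[pick[n_aging:]].tolist()
        counts = _betweenness_for_genes(adj, aging, pdm, genes)
        for g, obs in observed.items():
            if counts.get(g, 0) >= obs:
                exceed[g] += 1
    if smoothed:
        p_values = {g: (c + 1) / (reps + 1) for g, c in exceed.items()}
    else:
        p_values = {g: c / reps for g, c in exceed.items()}
    return PermutationResult(
        reps=reps, seed=seed, observed=dict(observed), exceed_counts=exceed,
        p_values=p_values, smoothed=smoothed,
    )


def pairs_to_frame(pairs: Iterable[MarkerPair]) -> pd.DataFrame:
    """Tabular export of marker pairs (path as '->'-joined string or NA)."""
    rows = []
    for p in pairs:
        rows.append(
            {
                "aging_marker": p.aging_marker,
                "pd_marker": p.pd_marker,
                "r_control": p.r_control,
                "r_pd": p.r_pd,
                "diff": p.diff,
                "abs_diff": p.abs_diff,
                "opposite_sign": p.opposite_sign,
                "path": "->".join(p.path) if p.path is not None else "NA",
                "path_length": p.path_length if p.path is not None else "NA",
                "is_max_diff": p.is_max_diff,
            }
        )
    return pd.DataFrame(rows)


def diff_matrix(pairs: Iterable[MarkerPair]) -> pd.DataFrame:
    """Aging x PD matrix of signed correlation differences (heatmap-ready)."""
    pairs = list(pairs)
    aging = sorted({p.aging_marker for p in pairs})
    pdm = sorted({p.pd_marker for p in pairs})
    mat = pd.DataFrame(np.nan, index=aging, columns=pdm)
    for p in pairs:
        mat.loc[p.aging_marker, p.pd_marker] = p.diff
    return mat
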