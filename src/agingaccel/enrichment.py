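"""Per-path hypergeometric gene-set enrichment with BH control.

Each aging-PD shortest path is tested against every gene set in a GMT
collection with the hypergeometric upper tail

    P(X >= k) = 1 - sum_{j=0}^{k-1} C(M, j) C(N-M, n-j) / C(N, n)

where N is the universe size, M the set size within the universe, n the
number of path genes in the universe and k the overlap.  p-values are BH
corrected across sets within each path; a row passes at p < 0.05 and
FDR < 0.1.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .network import bh_fdr
from .synthetic import GeneSetCollection

P_THRESHOLD = 0.05
Q_THRESHOLD = 0.1


def read_gmt(path, universe: Iterable[str] | None = None) -> GeneSetCollection:
    """Parse a GMT file (set name, description, tab-separated members).

    The universe defaults to the union of all members.  Malformed lines
    (fewer than two tab-separated fields or an empty set name) raise with the
    line number; duplicate members within a line are dropped (first kept).
    """
    text = Path(path).read_text()
    sets: dict[str, list[str]] = {}
    seen_any = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        seen_any = True
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 2:
            raise ValueError(f"malformed GMT line {lineno}: expected name, description, members")
        name = fields[0].strip()
        if not name:
            raise ValueError(f"malformed GMT line {lineno}: empty set name")
        members = list(dict.fromkeys(m for m in fields[2:] if m))
        sets[name] = members
    if not seen_any:
        raise ValueError(f"empty GMT file: {path}")
    if universe is None:
        uni = set().union(*(set(m) for m in sets.values())) if sets else set()
    else:
        uni = set(universe)
    return GeneSetCollection(sets=sets, universe=uni, source=str(path))


def hypergeom_upper_tail(N: int, M: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, M, n), computed in log space.

    k = 0 is the certain event (p = 1).
    """
    for name, value in {"N": N, "M": M, "n": n, "k": k}.items():
        if not isinstance(value, (int, np.integer)) or value < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {value!r}")
    if M > N or n > N:
        raise ValueError(f"M ({M}) and n ({n}) must not exceed N ({N})")
    if k > min(n, M):
        raise ValueError(f"k ({k}) must not exceed min(n, M) = {min(n, M)}")
    if k == 0:
        return 1.0
    return float(np.clip(stats.hypergeom.sf(k - 1, N, M, n), 0.0, 1.0))


def enrich_paths(
    paths: Mapping[str, Iterable[str]],
    collection: GeneSetCollection,
    universe: Iterable[str] | None = None,
    p_threshold: float = P_THRESHOLD,
    q_threshold: float = Q_THRESHOLD,
    bh_scope: str = "per_path",
) -> pd.DataFrame:
    """Test every (path, set) combination; BH across sets within each path.

    ``universe`` overrides the collection universe (e.g. restrict to network
    genes present in the GMT).  ``bh_scope='global'`` corrects across all
    (path, set) rows instead.  Returns rows
    (path_id, set, N, M, n, k, p, q, passed).
    """
    if not paths:
        raise ValueError("no paths supplied")
    if bh_scope not in ("per_path", "global"):
        raise ValueError(f"bh_scope must be per_path|global, got {bh_scope!r}")
    uni = set(universe) if universe is not None else set(collection.universe)
    N = len(uni)
    set_members = {name: set(m) & uni for name, m in collection.sets.items()}
    rows = []
    for path_id, genes in paths.items():
        path_genes = set(genes) & uni
        n = len(path_genes)
        for name, members in set_members.items():
            M = len(members)
            k = len(path_genes & members)
            p = hypergeom_upper_tail(N, M, n, k) if n > 0 else 1.0
            rows.append({"path_id": path_id, "set": name, "N": N, "M": M, "n": n, "k": k, "p": p})
    table = pd.DataFrame(rows)
    if bh_scope == "per_path":
        table["q"] = table.groupby("path_id", sort=False)["p"].transform(
            lambda s: bh_fdr(s.to_numpy())
        )
    else:
        table["q"] = bh_fdr(table["p"].to_numpy())
    table["passed"] = (table["p"] < p_threshold) & (table["q"] < q_threshold)
    return table


def summarize_enrichment(table: pd.DataFrame) -> pd.DataFrame:
    """Sets ranked by the number of paths they are enriched in (min p/q kept)."""
    passed = table[table["passed"]]
    if passed.empty:
        return pd.DataFrame(columns=["set", "n_enriched_paths", "min_p", "min_q"])
    summary = (
        passed.groupby("set")
        .agg(n_enriched_paths=("path_id", "nunique"), min_p=("p", "min"), min_q=("q", "min"))
        .reset_index()
        .sort_values(["n_enriched_paths", "min_p"], ascending=[False, True], kind="stable")
        .reset_index(drop=True)
    )
    return summary
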