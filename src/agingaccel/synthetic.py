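"""Synthetic multi-platform expression cohorts with planted structure.

Generates genes x samples expression matrices that mimic the statistical
structure of a multi-platform case/control brain-expression compendium:

* young (<50 y) and old (>=50 y) normal samples plus late-onset PD samples;
* a subset of genes whose mean tracks sigmoid-transformed age (aging genes);
* a subset of genes mean-shifted in PD (PD genes), optionally along a
  direction orthogonal to strong young-sample latent factors so that the
  shift only becomes visible after residualising on the young structure;
* gene pairs whose co-expression flips sign between control and PD
  (differential edges), built by sharing a latent factor with equal signs in
  controls and opposite signs in PD;
* additive per-(gene, platform) batch offsets and i.i.d. Gaussian noise.

Every planted feature is recorded in a :class:`GroundTruth` so recovery can
be measured downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .scoring import sigmoid_age

SAMPLE_COLUMNS = ["sample_id", "age", "group", "platform"]


@dataclass
class SyntheticConfig:
    """Parameters of the cohort generator.

    Defaults give a desk-scale analogue of the study cohort: ~420 samples in a
    425/447/392-like young:old:PD ratio, 300 genes across three platforms.
    ``aging_effect`` is the slope of the planted mean on the sigmoid-transformed
    age scale (expression units per transformed-age unit); ``pd_effect`` is the
    mean shift of PD genes in PD samples after removal of the masking latent
    structure; ``latent_corr_strength`` is the magnitude of the planted
    within-pair correlation (sign +rho in controls, -rho in PD).
    """

    n_genes: int = 300
    n_young: int = 140
    n_old_normal: int = 150
    n_pd: int = 130
    n_aging_genes: int = 30
    aging_effect: float = 3.0
    n_pd_genes: int = 14
    pd_effect: float = 1.0
    n_diff_edges: int = 20
    latent_corr_strength: float = 0.8
    platform_ids: tuple[str, ...] = ("GPL-A", "GPL-B", "GPL-C")
    platform_shift_sd: float = 0.5
    noise_sd: float = 1.0
    n_masking_factors: int = 3
    masking_latent_sd: float = 0.5
    edge_layout: str = "chain"  # "chain": aging-bridge-PD chains; "random": disjoint spare pairs
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "n_young": self.n_young,
            "n_old_normal": self.n_old_normal,
            "n_pd": self.n_pd,
            "n_aging_genes": self.n_aging_genes,
            "n_pd_genes": self.n_pd_genes,
            "n_diff_edges": self.n_diff_edges,
            "n_masking_factors": self.n_masking_factors,
        }
        for name, value in counts.items():
            if not isinstance(value, (int, np.integer)) or value < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {value!r}")
        if self.n_aging_genes + self.n_pd_genes > self.n_genes:
            raise ValueError("n_aging_genes + n_pd_genes must not exceed n_genes")
        if not 0.0 <= self.latent_corr_strength < 1.0:
            raise ValueError(
                f"latent_corr_strength must be in [0, 1), got {self.latent_corr_strength}"
            )
        if self.noise_sd <= 0:
            raise ValueError(f"noise_sd must be > 0, got {self.noise_sd}")
        if self.platform_shift_sd < 0:
            raise ValueError(f"platform_shift_sd must be >= 0, got {self.platform_shift_sd}")
        if self.masking_latent_sd < 0:
            raise ValueError(f"masking_latent_sd must be >= 0, got {self.masking_latent_sd}")
        if len(self.platform_ids) == 0:
            raise ValueError("platform_ids must be nonempty")
        if self.edge_layout not in ("chain", "random"):
            raise ValueError(f"edge_layout must be 'chain' or 'random', got {self.edge_layout!r}")
        if self.edge_layout == "chain":
            spare = self.n_genes - self.n_aging_genes - self.n_pd_genes
        else:
            spare = self.n_genes - self.n_aging_genes - self.n_pd_genes - 2 * self.n_diff_edges
        bridges = (self.n_diff_edges // 2) if self.edge_layout == "chain" else 0
        if self.edge_layout == "chain" and bridges + (self.n_diff_edges % 2) * 2 > max(spare, 0):
            raise ValueError("n_genes too small for the requested n_diff_edges chain layout")
        if self.edge_layout == "random" and spare < 0:
            raise ValueError("n_genes too small for the requested n_diff_edges")


@dataclass
class GroundTruth:
    """Planted structure of a generated cohort."""

    aging_gene_ids: set[str]
    pd_gene_ids: set[str]
    # unordered pair -> (target r in controls, target r in PD)
    diff_edge_pairs: dict[frozenset, tuple[float, float]]
    true_ages: dict[str, float]

    @property
    def diff_edge_genes(self) -> set[str]:
        return set().union(*self.diff_edge_pairs) if self.diff_edge_pairs else set()

    def to_json(self, path) -> None:
        payload = {
            "aging_gene_ids": sorted(self.aging_gene_ids),
            "pd_gene_ids": sorted(self.pd_gene_ids),
            "diff_edge_pairs": [
                {"genes": sorted(k), "r_control": v[0], "r_pd": v[1]}
                for k, v in sorted(self.diff_edge_pairs.items(), key=lambda kv: sorted(kv[0]))
            ],
            "true_ages": self.true_ages,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            aging_gene_ids=set(payload["aging_gene_ids"]),
            pd_gene_ids=set(payload["pd_gene_ids"]),
            diff_edge_pairs={
                frozenset(e["genes"]): (e["r_control"], e["r_pd"])
                for e in payload["diff_edge_pairs"]
            },
            true_ages={k: float(v) for k, v in payload["true_ages"].items()},
        )


def _gene_ids(n: int) -> list[str]:
    return [f"G{i + 1:04d}" for i in range(n)]


def _plan_edges(cfg: SyntheticConfig, genes: list[str]):
    """Assign differential-edge endpoints.

    Chain layout builds aging-bridge and bridge-PD pairs so marker genes are
    connected through interior nodes; random layout uses disjoint spare-gene
    pairs whose realised correlation is exactly +/-rho.
    """
    aging = genes[: cfg.n_aging_genes]
    pdg = genes[cfg.n_aging_genes : cfg.n_aging_genes + cfg.n_pd_genes]
    spare = list(genes[cfg.n_aging_genes + cfg.n_pd_genes :])
    pairs: list[tuple[str, str]] = []
    if cfg.edge_layout == "random":
        for i in range(cfg.n_diff_edges):
            pairs.append((spare[2 * i], spare[2 * i + 1]))
        return aging, pdg, pairs
    aging_pool = list(aging)
    pd_pool = list(pdg)
    n_chains = cfg.n_diff_edges // 2
    for _ in range(n_chains):
        a = aging_pool.pop(0) if aging_pool else spare.pop()
        p = pd_pool.pop(0) if pd_pool else spare.pop()
        m = spare.pop(0)
        pairs.append((a, m))
        pairs.append((m, p))
    if cfg.n_diff_edges % 2:
        pairs.append((spare.pop(0), spare.pop(0)))
    return aging, pdg, pairs


def generate_cohort(config: SyntheticConfig) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate (expression matrix, sample table, ground truth).

    The matrix is genes x samples; the table has columns sample_id, age,
    group, platform (age_class is derivable as young iff age < 50).
    Fully deterministic for a fixed config.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    n_samples = config.n_young + config.n_old_normal + config.n_pd
    sample_ids = [f"S{i + 1:04d}" for i in range(n_samples)]

    ages = np.concatenate(
        [
            rng.integers(20, 50, size=config.n_young),
            rng.integers(50, 96, size=config.n_old_normal),
            rng.integers(50, 96, size=config.n_pd),
        ]
    ).astype(float)
    groups = np.array(
        ["normal"] * (config.n_young + config.n_old_normal) + ["PD"] * config.n_pd
    )
    platforms = np.array(
        [config.platform_ids[i % len(config.platform_ids)] for i in range(n_samples)]
    )
    is_pd = groups == "PD"

    sigma = config.noise_sd
    expr = rng.normal(0.0, sigma, size=(config.n_genes, n_samples))
    gene_index = {g: i for i, g in enumerate(genes)}

    aging_genes, pd_genes, edge_pairs = _plan_edges(config, genes)

    # differential edges first: the latent-sharing transform rescales the
    # i.i.d. noise of its genes (variance-preserving), so it must precede the
    # deterministic mean terms.  Sign flips in PD on the second gene of a pair.
    rho = config.latent_corr_strength
    truth_pairs: dict[frozenset, tuple[float, float]] = {}
    if config.n_diff_edges > 0 and rho > 0:
        latent_count = {g: 0 for g in genes}
        for g1, g2 in edge_pairs:
            latent_count[g1] += 1
            latent_count[g2] += 1
        scaled: set[str] = set()
        w = sigma * np.sqrt(rho)
        for g1, g2 in edge_pairs:
            z = rng.normal(0.0, 1.0, size=n_samples)
            for g in (g1, g2):
                if g not in scaled:
                    expr[gene_index[g]] *= np.sqrt(1.0 - rho)
                    scaled.add(g)
            sign2 = np.where(is_pd, -1.0, 1.0)
            expr[gene_index[g1]] += w * z
            expr[gene_index[g2]] += w * sign2 * z
            var1 = (1.0 - rho) + rho * latent_count[g1]
            var2 = (1.0 - rho) + rho * latent_count[g2]
            r_target = rho / np.sqrt(var1 * var2)
            truth_pairs[frozenset((g1, g2))] = (float(r_target), float(-r_target))
    elif config.n_diff_edges > 0:
        for g1, g2 in edge_pairs:
            truth_pairs[frozenset((g1, g2))] = (0.0, 0.0)

    # aging genes: mean linear in sigmoid-transformed age
    tage = sigmoid_age(ages)
    for g in aging_genes:
        expr[gene_index[g]] += config.aging_effect * tage

    # masking latent factors shared by every sample (the young-sample
    # covariation the improved PD predictor removes); PD shift orthogonal
    shift = np.zeros(config.n_genes)
    for j, g in enumerate(pd_genes):
        shift[gene_index[g]] = config.pd_effect * (1.0 if j % 2 == 0 else -1.0)
    if config.n_masking_factors > 0 and config.masking_latent_sd > 0:
        loadings = rng.normal(
            0.0, config.masking_latent_sd, size=(config.n_genes, config.n_masking_factors)
        )
        norm = np.linalg.norm(shift)
        if norm > 0:
            unit = shift / norm
            loadings -= np.outer(unit, unit @ loadings)
        factors = rng.normal(0.0, 1.0, size=(config.n_masking_factors, n_samples))
        expr += loadings @ factors
    if is_pd.any():
        expr[:, is_pd] += shift[:, None]

    # per-(gene, platform) additive batch offsets
    if config.platform_shift_sd > 0:
        for plat in config.platform_ids:
            cols = platforms == plat
            if cols.any():
                expr[:, cols] += rng.normal(
                    0.0, config.platform_shift_sd, size=(config.n_genes, 1)
                )

    matrix = pd.DataFrame(expr, index=pd.Index(genes, name="GENE_SYMBOL"), columns=sample_ids)
    table = pd.DataFrame(
        {"sample_id": sample_ids, "age": ages, "group": groups, "platform": platforms}
    )
    truth = GroundTruth(
        aging_gene_ids=set(aging_genes),
        pd_gene_ids=set(pd_genes),
        diff_edge_pairs=truth_pairs,
        true_ages=dict(zip(sample_ids, ages.tolist())),
    )
    return matrix, table, truth


# ---------------------------------------------------------------------------
# cohort I/O (TSV layout mirroring a GEO-series-matrix-like export)
# ---------------------------------------------------------------------------

def write_cohort(
    matrix: pd.DataFrame,
    table: pd.DataFrame,
    truth: GroundTruth | None,
    directory,
) -> dict[str, Path]:
    """Write expression.tsv / samples.tsv (+ truth.json) into ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    _check_sample_consistency(matrix, table)
    paths = {
        "expression": directory / "expression.tsv",
        "samples": directory / "samples.tsv",
    }
    out = matrix.copy()
    out.index.name = "GENE_SYMBOL"
    out.to_csv(paths["expression"], sep="\t", float_format="%.17g")  # exact round-trip
    table[SAMPLE_COLUMNS].to_csv(paths["samples"], sep="\t", index=False)
    if truth is not None:
        paths["truth"] = directory / "truth.json"
        truth.to_json(paths["truth"])
    return paths


def read_cohort(directory) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a cohort written by :func:`write_cohort`; validates the schema."""
    directory = Path(directory)
    matrix = pd.read_csv(
        directory / "expression.tsv", sep="\t", index_col="GENE_SYMBOL",
        float_precision="round_trip",
    )
    if matrix.shape[1] == 0:  # pandas drops columns of an all-index file only if empty
        matrix = matrix.astype(float)
    table = pd.read_csv(directory / "samples.tsv", sep="\t")
    missing_cols = [c for c in SAMPLE_COLUMNS if c not in table.columns]
    if missing_cols:
        raise ValueError(f"sample table missing required columns: {missing_cols}")
    table["sample_id"] = table["sample_id"].astype(str)
    _check_sample_consistency(matrix, table)
    return matrix, table


def _check_sample_consistency(matrix: pd.DataFrame, table: pd.DataFrame) -> None:
    mat_ids = set(map(str, matrix.columns))
    tab_ids = set(map(str, table["sample_id"]))
    extra = sorted(mat_ids - tab_ids)
    missing = sorted(tab_ids - mat_ids)
    if extra or missing:
        raise ValueError(
            "matrix/table sample mismatch: "
            f"in matrix only {extra}; in table only {missing}"
        )


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    """Named gene sets over an explicit universe (GMT-compatible)."""

    sets: dict[str, list[str]]
    universe: set[str] = field(default_factory=set)
    source: str = ""

    def write_gmt(self, path) -> None:
        lines = []
        for name, members in self.sets.items():
            desc = self.source or "na"
            lines.append("\t".join([name, desc, *members]))
        Path(path).write_text("\n".join(lines) + "\n")


def generate_gene_sets(
    truth: GroundTruth,
    universe: Sequence[str],
    n_decoy_sets: int,
    set_size: int,
    seed: int,
) -> GeneSetCollection:
    """One planted set (differential-edge genes + padding) plus uniform decoys."""
    universe = list(universe)
    if set_size > len(universe):
        raise ValueError(
            f"set_size {set_size} exceeds universe size {len(universe)}"
        )
    rng = np.random.default_rng(seed)
    planted_core = sorted(g for g in truth.diff_edge_genes if g in set(universe))
    if len(planted_core) > set_size:
        raise ValueError(
            f"set_size {set_size} smaller than the {len(planted_core)} differential-edge genes"
        )
    remaining = sorted(set(universe) - set(planted_core))
    pad = rng.choice(remaining, size=set_size - len(planted_core), replace=False)
    planted = sorted(planted_core) + sorted(pad.tolist())
    sets = {"PLANTED_DIFF_EDGE_SET": planted}
    decoy_pool = sorted(set(universe) - set(planted))
    for i in range(n_decoy_sets):
        members = rng.choice(decoy_pool, size=min(set_size, len(decoy_pool)), replace=False)
        sets[f"DECOY_SET_{i + 1:03d}"] = sorted(members.tolist())
    return GeneSetCollection(sets=sets, universe=set(universe), source="synthetic")
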