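"""Calibration and recovery experiments on synthetic cohorts.

These experiments quantify whether the pipeline behaves correctly under known
conditions: null cohorts (no planted signal) must yield chance-level
classification and empty networks; cohorts with planted signal must return
the planted aging genes, differential edges and masked PD effects.  They are
used both by the test suite and by the acceptance script.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from . import network as net
from . import paths as bp
from . import predictors as pred
from . import scoring
from . import synthetic as syn


def null_config(seed: int, **overrides) -> syn.SyntheticConfig:
    """Zero-signal cohort: no aging, PD, differential-edge or latent structure."""
    base = dict(
        n_genes=60, n_young=100, n_old_normal=100, n_pd=0,
        n_aging_genes=0, aging_effect=0.0, n_pd_genes=0, pd_effect=0.0,
        n_diff_edges=0, masking_latent_sd=0.0, platform_shift_sd=0.0,
    )
    base.update(overrides)
    return syn.SyntheticConfig(seed=seed, **base)


@dataclass
class NullCalibration:
    cv_accuracies: list[float]
    edge_counts: list[int]
    band: tuple[float, float]

    @property
    def frac_within_band(self) -> float:
        lo, hi = self.band
        return float(np.mean([(lo <= a <= hi) for a in self.cv_accuracies]))

    @property
    def frac_zero_edges(self) -> float:
        return float(np.mean([c == 0 for c in self.edge_counts]))

    @property
    def frac_joint(self) -> float:
        lo, hi = self.band
        ok = [
            lo <= a <= hi and c == 0
            for a, c in zip(self.cv_accuracies, self.edge_counts)
        ]
        return float(np.mean(ok))


def null_calibration(n_seeds: int = 20, base_seed: int = 0) -> NullCalibration:
    """CV accuracy and network edge counts on zero-signal cohorts.

    Per seed two null cohorts are drawn: 100 young + 100 old normal samples
    for the aging-predictor CV check (chance band 0.5 +/- 3 * 0.5/sqrt(100),
    the 3-binomial-SD band at the per-class sample count, i.e. [0.35, 0.65]),
    and 150 control + 130 PD samples (the default cohort group sizes) for the
    network check at the standard thresholds (|delta| > 0.5, BH-FDR < 0.05),
    where the expected edge count is 0.
    """
    accs, edges = [], []
    for i in range(n_seeds):
        cfg = null_config(base_seed + 1000 + i)
        matrix, table, _ = syn.generate_cohort(cfg)
        meta = table.set_index("sample_id")
        normal = [c for c in matrix.columns if meta.loc[c, "group"] == "normal"]
        labels = (meta.loc[normal, "age"] >= 50).astype(int).to_numpy()
        curve = pred.cross_validate_feature_counts(
            matrix[normal], labels, max_features=min(100, cfg.n_genes),
            seed=base_seed + 2000 + i,
        )
        accs.append(curve.selected_accuracy)

        net_cfg = null_config(
            base_seed + 1500 + i, n_young=0, n_old_normal=150, n_pd=130
        )
        nm, nt, _ = syn.generate_cohort(net_cfg)
        nmeta = nt.set_index("sample_id")
        old = [c for c in nm.columns if nmeta.loc[c, "group"] == "normal"]
        pdc = [c for c in nm.columns if nmeta.loc[c, "group"] == "PD"]
        rng = np.random.default_rng(base_seed + 3000 + i)
        network = net.build_network(
            nm[old], nm[pdc], rng.normal(size=len(old)), rng.normal(size=len(pdc))
        )
        edges.append(network.graph.number_of_edges())
    half_width = 3 * 0.5 / np.sqrt(100)
    return NullCalibration(accs, edges, (0.5 - half_width, 0.5 + half_width))


def aging_marker_recovery(
    n_seeds: int = 10, base_seed: int = 0, n_per_group: int = 150
) -> list[float]:
    """Fraction of planted aging genes ranked in the top 2x planted count.

    Conditions: aging_effect = 2 * noise_sd, n >= 100 samples per age class.
    """
    fractions = []
    for i in range(n_seeds):
        cfg = syn.SyntheticConfig(
            n_genes=300, n_young=n_per_group, n_old_normal=n_per_group, n_pd=0,
            n_aging_genes=30, aging_effect=2.0, noise_sd=1.0,
            n_pd_genes=0, pd_effect=0.0, n_diff_edges=0,
            masking_latent_sd=0.0, platform_shift_sd=0.0,
            seed=base_seed + 4000 + i,
        )
        matrix, table, truth = syn.generate_cohort(cfg)
        labels = (table.set_index("sample_id").loc[matrix.columns, "age"] >= 50).astype(int)
        ranked = pred.rank_genes_by_correlation(matrix, labels.to_numpy())
        top = set(ranked["gene"].head(2 * cfg.n_aging_genes))
        fractions.append(len(truth.aging_gene_ids & top) / cfg.n_aging_genes)
    return fractions


def aging_score_recovery(n_seeds: int = 20, base_seed: int = 0, n: int = 200) -> list[float]:
    """Pearson correlation between fitted scores and true transformed age.

    Markers are linear in transformed age with noise at 0.2x the signal SD.
    """
    out = []
    for i in range(n_seeds):
        rng = np.random.default_rng(base_seed + 5000 + i)
        ages = rng.integers(20, 96, size=n).astype(float)
        t = scoring.sigmoid_age(ages)
        n_markers = 10
        B = rng.normal(1.0, 0.3, size=n_markers)
        signal = np.outer(B, t)
        noise = rng.normal(0.0, 0.2 * signal.std(), size=signal.shape)
        matrix = pd.DataFrame(
            signal + noise,
            index=[f"M{j:02d}" for j in range(n_markers)],
            columns=[f"S{j:03d}" for j in range(n)],
        )
        model = scoring.fit_aging_score(matrix, ages)
        scores = scoring.score_samples(model, matrix)
        out.append(float(np.corrcoef(scores, t)[0, 1]))
    return out


@dataclass
class EdgeRecovery:
    sensitivities: list[float]
    false_edge_counts: list[int]


def edge_recovery(n_seeds: int = 10, base_seed: int = 0) -> EdgeRecovery:
    """Planted sign-flip edge recovery at |r| = 0.8, 300 genes, 150 per group."""
    sens, fps = [], []
    for i in range(n_seeds):
        cfg = syn.SyntheticConfig(
            n_genes=300, n_young=0, n_old_normal=150, n_pd=150,
            n_aging_genes=0, aging_effect=0.0, n_pd_genes=0, pd_effect=0.0,
            n_diff_edges=20, latent_corr_strength=0.8, noise_sd=1.0,
            edge_layout="random", masking_latent_sd=0.0, platform_shift_sd=0.0,
            seed=base_seed + 6000 + i,
        )
        matrix, table, truth = syn.generate_cohort(cfg)
        meta = table.set_index("sample_id")
        ctl = [c for c in matrix.columns if meta.loc[c, "group"] == "normal"]
        pdc = [c for c in matrix.columns if meta.loc[c, "group"] == "PD"]
        rng = np.random.default_rng(base_seed + 7000 + i)
        network = net.build_network(
            matrix[ctl], matrix[pdc], rng.normal(size=len(ctl)), rng.normal(size=len(pdc))
        )
        found = network.edge_set
        planted = set(truth.diff_edge_pairs)
        sens.append(len(found & planted) / len(planted))
        fps.append(len(found - planted))
    return EdgeRecovery(sens, fps)


def paired_predictor_comparison(
    n_seeds: int = 5, base_seed: int = 0
) -> list[tuple[float, float]]:
    """(improved, traditional) CV accuracy pairs on the masking construction.

    The PD mean shift lies orthogonal to three strong young-sample latent
    factors (loading SD 2x the noise SD), so it is masked in the original
    data and exposed by young-PC residualization.
    """
    out = []
    for i in range(n_seeds):
        cfg = syn.SyntheticConfig(
            n_genes=200, n_young=120, n_old_normal=120, n_pd=120,
            n_aging_genes=0, aging_effect=0.0,
            n_pd_genes=14, pd_effect=1.0,
            n_diff_edges=0, platform_shift_sd=0.0,
            n_masking_factors=3, masking_latent_sd=2.0,
            seed=base_seed + 8000 + i,
        )
        matrix, table, _ = syn.generate_cohort(cfg)
        seed = base_seed + 9000 + i
        improved = pred.train_improved_pd_predictor(matrix, table, seed)
        traditional = pred.train_traditional_pd_predictor(matrix, table, seed)
        out.append((improved.curve.selected_accuracy, traditional.curve.selected_accuracy))
    return out


def permutation_pvalue_uniformity(
    n_evaluations: int = 200, reps: int = 100, base_seed: int = 0
) -> tuple[float, list[float]]:
    """KS distance of permutation p-values of a random gene from Uniform(0, 1).

    Each evaluation draws a fresh random regular graph, random marker sets and
    a random non-marker focal gene, computes the focal gene's observed path
    betweenness, and its permutation p-value.  Under the null the observed
    betweenness and the permutation draws are exchangeable, so the p-value is
    uniform up to discreteness; a regular graph keeps the betweenness
    distribution spread out (no isolated low-degree nodes pinning mass at
    p = 1), which keeps the discreteness error small.
    """
    n_nodes, degree = 40, 3
    n_aging, n_pd = 20, 8
    pvals = []
    for i in range(n_evaluations):
        rng = np.random.default_rng(base_seed + 10_000 + i)
        graph = nx.random_regular_graph(degree, n_nodes, seed=int(rng.integers(2 ** 31 - 1)))
        graph = nx.relabel_nodes(graph, {j: f"G{j:03d}" for j in range(n_nodes)})
        nodes = sorted(graph.nodes)
        pick = rng.choice(len(nodes), size=n_aging + n_pd + 1, replace=False)
        aging = [nodes[j] for j in pick[:n_aging]]
        pdm = [nodes[j] for j in pick[n_aging:n_aging + n_pd]]
        focal = nodes[pick[-1]]
        pairs = bp.shortest_paths(graph, aging, pdm)
        observed = bp.path_betweenness(pairs).lookup().get(focal, 0)
        perm = bp.permutation_test(
            graph, n_aging, n_pd, {focal: observed}, reps=reps,
            seed=int(rng.integers(2 ** 31 - 1)),
        )
        pvals.append(perm.p_values[focal])
    pvals_sorted = np.sort(pvals)
    grid = np.arange(1, len(pvals_sorted) + 1) / len(pvals_sorted)
    ks = float(np.max(np.maximum(
        np.abs(grid - pvals_sorted),
        np.abs(grid - 1 / len(pvals_sorted) - pvals_sorted),
    )))
    return ks, pvals
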