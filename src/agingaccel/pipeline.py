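"""End-to-end orchestration of the accelerated-aging analysis.

Stage order: simulate (or load) -> preprocess -> predictors (aging, improved
PD, traditional PD) -> aging scores -> aging-acceleration networks (train +
test replicate, Fisher similarity, scale-free check) -> aging-PD bipartite
paths (retention, linkage, betweenness, permutation) -> per-path enrichment.
Every stage writes plain-text artifacts into the run directory and records
its parameters in a JSON manifest; the whole run is deterministic under the
configured seed (one global seed fanned out to per-stage seeds by fixed
offsets so stages can be re-run alone).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import enrichment as enr
from . import network as net
from . import paths as bp
from . import predictors as pred
from . import preprocess as prep
from . import scoring
from . import synthetic as syn

logger = logging.getLogger(__name__)

# fixed per-stage seed offsets (stable stage-level reproducibility)
SEED_OFFSETS = {
    "simulate": 11,
    "gene_sets": 23,
    "aging": 37,
    "pd_improved": 53,
    "pd_traditional": 53,  # shared split/CV seed: paired comparison on identical folds
    "permutation": 71,
}


@dataclass
class PipelineConfig:
    """All pipeline parameters; defaults follow the study values."""

    out_dir: str = "agingaccel_run"
    seed: int = 0
    synthetic: syn.SyntheticConfig = field(default_factory=syn.SyntheticConfig)
    expression_path: str | None = None  # user data overrides the generator
    samples_path: str | None = None
    gmt_path: str | None = None
    knn_k: int = 5
    cv_folds: int = 10
    max_features: int = 100
    rank_once: bool = False
    age_cutoff: float = 50.0
    sigmoid_center: float = 50.0
    sigmoid_scale: float = 50.0
    zero_fraction: float = 0.30
    fit_scores_on: str = "normal"  # or "all"
    delta_threshold: float = 0.5
    fdr_threshold: float = 0.05
    significance_mode: str = "any"
    max_network_genes: int = 2000
    perm_reps: int = 1000
    perm_top: int = 10
    enrich_p: float = 0.05
    enrich_q: float = 0.1
    universe_mode: str = "network"  # or "gmt_union"
    n_decoy_sets: int = 20
    set_size: int = 40

    def validate(self) -> None:
        self.synthetic.validate()
        checks = [
            ("knn_k", self.knn_k >= 1),
            ("cv_folds", self.cv_folds >= 2),
            ("max_features", self.max_features >= 1),
            ("age_cutoff", np.isfinite(self.age_cutoff) and self.age_cutoff > 0),
            ("sigmoid_scale", self.sigmoid_scale > 0),
            ("zero_fraction", 0 <= self.zero_fraction <= 1),
            ("delta_threshold", 0 <= self.delta_threshold <= 2),
            ("fdr_threshold", 0 < self.fdr_threshold <= 1),
            ("significance_mode", self.significance_mode in ("any", "all", "off")),
            ("perm_reps", self.perm_reps >= 1),
            ("perm_top", self.perm_top >= 1),
            ("enrich_p", 0 < self.enrich_p <= 1),
            ("enrich_q", 0 < self.enrich_q <= 1),
            ("fit_scores_on", self.fit_scores_on in ("normal", "all")),
            ("universe_mode", self.universe_mode in ("network", "gmt_union")),
            ("max_network_genes", self.max_network_genes >= 2),
        ]
        for name, ok in checks:
            if not ok:
                raise ValueError(f"invalid configuration value for {name}: {getattr(self, name)!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        raw = dict(raw)
        syn_raw = raw.pop("synthetic", {})
        syn_known = {f.name for f in dataclasses.fields(syn.SyntheticConfig)}
        syn_unknown = set(syn_raw) - syn_known
        if syn_unknown:
            raise ValueError(f"unknown synthetic configuration keys: {sorted(syn_unknown)}")
        if "platform_ids" in syn_raw:
            syn_raw["platform_ids"] = tuple(syn_raw["platform_ids"])
        cfg = cls(synthetic=syn.SyntheticConfig(**syn_raw), **raw)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["synthetic"]["platform_ids"] = list(self.synthetic.platform_ids)
        return d


def _stage_seed(cfg: PipelineConfig, stage: str) -> int:
    return (cfg.seed * 1000 + SEED_OFFSETS[stage]) % (2 ** 31 - 1)


def setup_logging(out_dir: Path | None = None, level: int = logging.INFO) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        handlers.append(logging.FileHandler(out_dir / "run.log", mode="a"))
    logging.basicConfig(
        level=level, handlers=handlers, force=True,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


# ---------------------------------------------------------------------------
# stages (each reads its inputs from the run directory and writes artifacts)
# ---------------------------------------------------------------------------

def stage_simulate(cfg: PipelineConfig) -> dict:
    out = Path(cfg.out_dir) / "cohort"
    if cfg.expression_path and cfg.samples_path:
        matrix = pd.read_csv(cfg.expression_path, sep="\t", index_col="GENE_SYMBOL")
        table = pd.read_csv(cfg.samples_path, sep="\t")
        truth = None
    else:
        sim_cfg = dataclasses.replace(cfg.synthetic, seed=_stage_seed(cfg, "simulate"))
        matrix, table, truth = syn.generate_cohort(sim_cfg)
    files = syn.write_cohort(matrix, table, truth, out)
    if cfg.gmt_path:
        sets = enr.read_gmt(cfg.gmt_path)
    elif truth is not None:
        sets = syn.generate_gene_sets(
            truth, list(matrix.index), cfg.n_decoy_sets, cfg.set_size,
            seed=_stage_seed(cfg, "gene_sets"),
        )
    else:
        sets = None
    if sets is not None:
        sets.write_gmt(out / "sets.gmt")
        files["gene_sets"] = out / "sets.gmt"
    return {"outputs": {k: str(v) for k, v in files.items()},
            "n_genes": int(matrix.shape[0]), "n_samples": int(matrix.shape[1])}


def stage_preprocess(cfg: PipelineConfig) -> dict:
    run = Path(cfg.out_dir)
    matrix, table = syn.read_cohort(run / "cohort")
    matrix = prep.fill_and_filter_genes(matrix, cfg.zero_fraction)
    matrix, table = prep.filter_samples(matrix, table, cfg.age_cutoff)
    matrix = prep.normalize_platform(matrix, table)
    out = run / "preprocess"
    out.mkdir(parents=True, exist_ok=True)
    matrix.to_csv(out / "normalized.tsv", sep="\t")
    table.to_csv(out / "samples.tsv", sep="\t", index=False)
    return {
        "outputs": {"normalized": str(out / "normalized.tsv"), "samples": str(out / "samples.tsv")},
        "n_genes_kept": int(matrix.shape[0]),
        "n_samples_kept": int(matrix.shape[1]),
    }


def _load_preprocessed(cfg: PipelineConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    out = Path(cfg.out_dir) / "preprocess"
    matrix = pd.read_csv(out / "normalized.tsv", sep="\t", index_col="GENE_SYMBOL")
    table = pd.read_csv(out / "samples.tsv", sep="\t")
    table["sample_id"] = table["sample_id"].astype(str)
    return matrix, table


def _predictor_kwargs(cfg: PipelineConfig) -> dict:
    return dict(
        k=cfg.knn_k, folds=cfg.cv_folds, max_features=cfg.max_features,
        rank_once=cfg.rank_once,
    )


def _write_predictor(result: pred.PredictorResult, out: Path) -> dict:
    prefix = result.task.replace("-", "_")
    files = {}
    result.ranking.to_csv(out / f"{prefix}_ranked.tsv", sep="\t", index=False)
    result.curve.to_frame().to_csv(out / f"{prefix}_curve.tsv", sep="\t", index=False)
    result.roc.to_frame().to_csv(out / f"{prefix}_roc.tsv", sep="\t", index=False)
    metrics = {
        "selected_n": result.curve.selected_n,
        "cv_accuracy": result.curve.selected_accuracy,
        "test_accuracy": result.roc.accuracy,
        "auc": None if np.isnan(result.roc.auc) else result.roc.auc,
        "markers": result.marker_genes,
        "train_ids": result.train_ids,
        "test_ids": result.test_ids,
    }
    (out / f"{prefix}_metrics.json").write_text(json.dumps(metrics, indent=1))
    for kind in ("ranked", "curve", "roc", "metrics"):
        suffix = "json" if kind == "metrics" else "tsv"
        files[f"{prefix}_{kind}"] = str(out / f"{prefix}_{kind}.{suffix}")
    return files


def stage_predict(cfg: PipelineConfig) -> dict:
    matrix, table = _load_preprocessed(cfg)
    out = Path(cfg.out_dir) / "predict"
    out.mkdir(parents=True, exist_ok=True)
    kwargs = _predictor_kwargs(cfg)
    aging = pred.train_aging_predictor(
        matrix, table, _stage_seed(cfg, "aging"), cfg.age_cutoff, **kwargs
    )
    improved = pred.train_improved_pd_predictor(
        matrix, table, _stage_seed(cfg, "pd_improved"), cfg.age_cutoff, **kwargs
    )
    traditional = pred.train_traditional_pd_predictor(
        matrix, table, _stage_seed(cfg, "pd_traditional"), cfg.age_cutoff, **kwargs
    )
    files = {}
    summary = {}
    for result in (aging, improved, traditional):
        files.update(_write_predictor(result, out))
        summary[result.task] = {
            "selected_n": result.curve.selected_n,
            "cv_accuracy": result.curve.selected_accuracy,
            "test_accuracy": result.roc.accuracy,
            "auc": None if np.isnan(result.roc.auc) else result.roc.auc,
        }
    return {"outputs": files, "summary": summary}


def _load_metrics(cfg: PipelineConfig, task: str) -> dict:
    path = Path(cfg.out_dir) / "predict" / f"{task}_metrics.json"
    return json.loads(path.read_text())


def stage_score(cfg: PipelineConfig) -> dict:
    matrix, table = _load_preprocessed(cfg)
    aging = _load_metrics(cfg, "aging")
    markers = aging["markers"]
    meta = table.set_index("sample_id")
    if cfg.fit_scores_on == "normal":
        fit_ids = [c for c in matrix.columns if meta.loc[c, "group"] == "normal"]
    else:
        fit_ids = list(matrix.columns)
    model = scoring.fit_aging_score(
        matrix.loc[markers, fit_ids], meta.loc[fit_ids, "age"],
        center=cfg.sigmoid_center, scale=cfg.sigmoid_scale,
    )
    scores = scoring.score_samples(model, matrix)
    comparison = scoring.compare_groups(scores, table)
    out = Path(cfg.out_dir) / "score"
    out.mkdir(parents=True, exist_ok=True)
    score_table = pd.DataFrame(
        {
            "sample_id": scores.index,
            "age": meta.loc[scores.index, "age"].to_numpy(),
            "group": meta.loc[scores.index, "group"].to_numpy(),
            "aging_score": scores.to_numpy(),
        }
    )
    score_table.to_csv(out / "scores.tsv", sep="\t", index=False)
    comparison.to_tsv(out / "group_comparison.tsv")
    sig = comparison.table.dropna(subset=["p_value"])
    return {
        "outputs": {"scores": str(out / "scores.tsv"),
                    "group_comparison": str(out / "group_comparison.tsv")},
        "n_markers": len(markers),
        "n_thresholds_significant": int((sig["p_value"] < 0.05).sum()),
        "n_thresholds_tested": int(len(sig)),
    }


def _split_samples(cfg: PipelineConfig, matrix, table):
    """Control/PD columns for the train and test networks, from the PD split."""
    improved = _load_metrics(cfg, "pd_improved")
    meta = table.set_index("sample_id")
    groups = {}
    for name, ids in (("train", improved["train_ids"]), ("test", improved["test_ids"])):
        ids = [i for i in ids if i in matrix.columns]
        groups[name] = {
            "control": [i for i in ids if meta.loc[i, "group"] == "normal"],
            "pd": [i for i in ids if meta.loc[i, "group"] == "PD"],
        }
    return groups


def stage_network(cfg: PipelineConfig) -> dict:
    matrix, table = _load_preprocessed(cfg)
    scores = pd.read_csv(Path(cfg.out_dir) / "score" / "scores.tsv", sep="\t")
    scores = pd.Series(
        scores["aging_score"].to_numpy(), index=scores["sample_id"].astype(str)
    )
    splits = _split_samples(cfg, matrix, table)
    out = Path(cfg.out_dir) / "network"
    out.mkdir(parents=True, exist_ok=True)
    nets = {}
    for name, cols in splits.items():
        nets[name] = net.build_network(
            matrix[cols["control"]], matrix[cols["pd"]],
            scores.loc[cols["control"]], scores.loc[cols["pd"]],
            delta_threshold=cfg.delta_threshold, fdr_threshold=cfg.fdr_threshold,
            significance_mode=cfg.significance_mode, max_genes=cfg.max_network_genes,
        )
        nets[name].to_tsv(out / f"edges_{name}.tsv")
        adjacency = nx_adjacency_frame(nets[name])
        adjacency.to_csv(out / f"adjacency_{name}.tsv", sep="\t", index=False)
    odds, fisher_p = net.network_similarity_fisher(nets["train"], nets["test"])
    sf_r, sf_p = net.scale_free_check(nets["train"])
    report = {
        "edges_train": int(nets["train"].graph.number_of_edges()),
        "edges_test": int(nets["test"].graph.number_of_edges()),
        "fisher_odds_ratio": None if not np.isfinite(odds) else odds,
        "fisher_p": fisher_p,
        "scale_free_r": None if np.isnan(sf_r) else sf_r,
        "scale_free_p": None if np.isnan(sf_p) else sf_p,
    }
    (out / "similarity.json").write_text(json.dumps(report, indent=1))
    return {
        "outputs": {
            "edges_train": str(out / "edges_train.tsv"),
            "edges_test": str(out / "edges_test.tsv"),
            "similarity": str(out / "similarity.json"),
        },
        **report,
    }


def nx_adjacency_frame(network: net.DifferentialNetwork) -> pd.DataFrame:
    return pd.DataFrame(
        [(a, b) for a, b in sorted(map(sorted, network.graph.edges()))],
        columns=["gene_a", "gene_b"],
    )


def _load_network(cfg: PipelineConfig, name: str) -> net.DifferentialNetwork:
    import networkx as nx

    out = Path(cfg.out_dir) / "network"
    edges = pd.read_csv(out / f"edges_{name}.tsv", sep="\t")
    graph = nx.Graph()
    for row in edges.itertuples(index=False):
        graph.add_edge(row.gene_a, row.gene_b)
    matrix, _ = _load_preprocessed(cfg)
    return net.DifferentialNetwork(graph=graph, edges=edges, universe=list(matrix.index))


def stage_paths(cfg: PipelineConfig) -> dict:
    matrix, table = _load_preprocessed(cfg)
    network = _load_network(cfg, "train")
    aging_markers = _load_metrics(cfg, "aging")["markers"]
    pd_markers = _load_metrics(cfg, "pd_improved")["markers"]
    pd_markers = [m for m in pd_markers if m not in set(aging_markers)]
    splits = _split_samples(cfg, matrix, table)
    ctl_cols, pd_cols = splits["train"]["control"], splits["train"]["pd"]
    r_control, _ = net.pairwise_correlation(matrix[ctl_cols])
    r_pd, _ = net.pairwise_correlation(matrix[pd_cols])

    pairs = bp.shortest_paths(network, aging_markers, pd_markers)
    pairs = bp.annotate_pair_correlations(pairs, r_control, r_pd)
    retained = bp.retain_opposite_sign_pairs(pairs)
    aging_link, pd_link, top_aging, top_pd = bp.marker_linkage_scores(retained)
    betweenness = bp.path_betweenness(p for p in retained if p.path is not None)

    out = Path(cfg.out_dir) / "paths"
    out.mkdir(parents=True, exist_ok=True)
    bp.pairs_to_frame(pairs).to_csv(out / "pairs.tsv", sep="\t", index=False)
    bp.diff_matrix(pairs).to_csv(out / "diff_matrix.tsv", sep="\t")
    aging_link.rename("linkage").to_csv(out / "linkage_aging.tsv", sep="\t")
    pd_link.rename("linkage").to_csv(out / "linkage_pd.tsv", sep="\t")

    top = betweenness.table.head(cfg.perm_top)
    n_aging_in = len([m for m in aging_markers if m in network.graph])
    n_pd_in = len([m for m in pd_markers if m in network.graph])
    n_nodes = network.graph.number_of_nodes()
    perm_frame = top.assign(perm_p=np.nan)
    if len(top) > 0 and 0 < n_aging_in and 0 < n_pd_in and n_aging_in + n_pd_in <= n_nodes:
        perm = bp.permutation_test(
            network, n_aging_in, n_pd_in,
            dict(zip(top["gene"], top["betweenness"])),
            reps=cfg.perm_reps, seed=_stage_seed(cfg, "permutation"),
        )
        perm_frame = perm.to_frame()
    elif len(top) > 0:
        logger.warning("permutation test skipped: marker counts exceed network size")
    bt = betweenness.table.merge(perm_frame[["gene", "perm_p"]] if "perm_p" in perm_frame
                                 else perm_frame, on="gene", how="left")
    bt.to_csv(out / "betweenness.tsv", sep="\t", index=False)

    n_with_path = sum(1 for p in pairs if p.path is not None)
    return {
        "outputs": {
            "pairs": str(out / "pairs.tsv"),
            "betweenness": str(out / "betweenness.tsv"),
            "linkage_aging": str(out / "linkage_aging.tsv"),
            "linkage_pd": str(out / "linkage_pd.tsv"),
        },
        "n_candidate_pairs": len(pairs),
        "n_pairs_with_path": n_with_path,
        "n_retained_pairs": len(retained),
        "top_linkage_aging": top_aging,
        "top_linkage_pd": top_pd,
        "top_betweenness": (
            {"gene": str(bt.iloc[0]["gene"]), "betweenness": int(bt.iloc[0]["betweenness"])}
            if len(bt) else None
        ),
    }


def stage_enrich(cfg: PipelineConfig) -> dict:
    run = Path(cfg.out_dir)
    pairs = pd.read_csv(run / "paths" / "pairs.tsv", sep="\t")
    collection = enr.read_gmt(run / "cohort" / "sets.gmt")
    matrix, _ = _load_preprocessed(cfg)
    network = _load_network(cfg, "train")
    if cfg.universe_mode == "network":
        universe = set(network.graph.nodes) & collection.universe
        if not universe:  # tiny networks may miss the GMT entirely
            universe = collection.universe
    else:
        universe = collection.universe
    with_path = pairs[
        pairs["path"].notna() & (pairs["path"] != "NA") & pairs["opposite_sign"]
    ]
    path_map = {
        f"{row.aging_marker}->{row.pd_marker}": row.path.split("->")
        for row in with_path.itertuples(index=False)
    }
    out = run / "enrich"
    out.mkdir(parents=True, exist_ok=True)
    if not path_map:
        logger.warning("no retained aging-PD paths; enrichment skipped")
        empty = pd.DataFrame(columns=["path_id", "set", "N", "M", "n", "k", "p", "q", "passed"])
        empty.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        enr.summarize_enrichment(empty.assign(passed=False)).to_csv(
            out / "summary.tsv", sep="\t", index=False
        )
        return {"outputs": {"enrichment": str(out / "enrichment.tsv")},
                "n_paths_tested": 0, "n_passing_rows": 0}
    table = enr.enrich_paths(
        path_map, collection, universe=universe,
        p_threshold=cfg.enrich_p, q_threshold=cfg.enrich_q,
    )
    table.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    summary = enr.summarize_enrichment(table)
    summary.to_csv(out / "summary.tsv", sep="\t", index=False)
    return {
        "outputs": {"enrichment": str(out / "enrichment.tsv"),
                    "summary": str(out / "summary.tsv")},
        "n_paths_tested": int(table["path_id"].nunique()),
        "n_passing_rows": int(table["passed"].sum()),
        "top_set": str(summary.iloc[0]["set"]) if len(summary) else None,
    }


STAGES = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "predict": stage_predict,
    "score": stage_score,
    "network": stage_network,
    "paths": stage_paths,
    "enrich": stage_enrich,
}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in order and write the manifest. Returns the manifest."""
    config.validate()
    run = Path(config.out_dir)
    run.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"parameters": config.to_dict(), "seed": config.seed, "stages": {}}
    for name, fn in STAGES.items():
        logger.info("stage %s", name)
        try:
            manifest["stages"][name] = fn(config)
        except Exception as exc:
            manifest["stages"][name] = {"error": str(exc)}
            (run / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
    (run / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def make_figures(run_dir) -> list[Path]:
    """Presentational plots: learning curve, ROC, score boxplots, degree log-log."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    run = Path(run_dir)
    fig_dir = run / "figures"
    fig_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    curve_path = run / "predict" / "aging_curve.tsv"
    if curve_path.exists():
        curve = pd.read_csv(curve_path, sep="\t")
        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.plot(curve["n_features"], curve["mean_cv_accuracy"])
        ax.set_xlabel("number of top-ranked genes")
        ax.set_ylabel("mean 10-fold CV accuracy")
        ax.set_title("Aging predictor learning curve")
        fig.tight_layout()
        out = fig_dir / "learning_curve.png"
        fig.savefig(out, dpi=120)
        plt.close(fig)
        written.append(out)
    else:
        logger.warning("learning-curve input missing; plot skipped")

    roc_path = run / "predict" / "aging_roc.tsv"
    if roc_path.exists():
        roc = pd.read_csv(roc_path, sep="\t")
        fig, ax = plt.subplots(figsize=(4, 4))
        if len(roc):
            ax.plot(roc["fpr"], roc["tpr"])
        else:
            ax.text(0.5, 0.5, "ROC undefined", ha="center")
            logger.warning("empty ROC table; placeholder drawn")
        ax.plot([0, 1], [0, 1], ls="--", c="grey")
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.set_title("Aging predictor ROC")
        fig.tight_layout()
        out = fig_dir / "roc_curve.png"
        fig.savefig(out, dpi=120)
        plt.close(fig)
        written.append(out)
    else:
        logger.warning("ROC input missing; plot skipped")

    scores_path = run / "score" / "scores.tsv"
    if scores_path.exists():
        scores = pd.read_csv(scores_path, sep="\t")
        thresholds = scoring.DEFAULT_THRESHOLDS
        fig, axes = plt.subplots(2, 4, figsize=(12, 6), sharey=True)
        for ax, t in zip(axes.ravel(), thresholds):
            sub = scores[scores["age"] >= t]
            data = [sub.loc[sub["group"] == g, "aging_score"] for g in ("normal", "PD")]
            ax.boxplot([d if len(d) else [np.nan] for d in data], tick_labels=["normal", "PD"])
            ax.set_title(f"age >= {t}")
        fig.suptitle("Aging scores by cumulative age group")
        fig.tight_layout()
        out = fig_dir / "score_boxplots.png"
        fig.savefig(out, dpi=120)
        plt.close(fig)
        written.append(out)
    else:
        logger.warning("scores missing; boxplot skipped")

    edges_path = run / "network" / "edges_train.tsv"
    if edges_path.exists():
        edges = pd.read_csv(edges_path, sep="\t")
        if len(edges):
            import networkx as nx

            g = nx.Graph(list(zip(edges["gene_a"], edges["gene_b"])))
            degs = np.array([d for _, d in g.degree()])
            values, counts = np.unique(degs, return_counts=True)
            fig, ax = plt.subplots(figsize=(4.5, 4))
            ax.scatter(np.log10(values), np.log10(counts))
            ax.set_xlabel("log10 degree")
            ax.set_ylabel("log10 frequency")
            ax.set_title("Degree distribution")
            fig.tight_layout()
            out = fig_dir / "degree_distribution.png"
            fig.savefig(out, dpi=120)
            plt.close(fig)
            written.append(out)
        else:
            logger.warning("network has no edges; degree plot skipped")
    else:
        logger.warning("network edges missing; degree plot skipped")
    return written
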