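"""Correlation statistics, BH-FDR, differential network, Fisher, scale-free."""

import itertools
from math import comb

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from agingaccel import network as net
from agingaccel import synthetic as syn

from conftest import make_matrix


# ---------------------------------------------------------------------------
# Pearson and partial correlation
# ---------------------------------------------------------------------------

def test_pairwise_correlation_examples(rng):
    g1 = rng.normal(size=20)
    matrix = make_matrix(np.vstack([g1, -g1, np.full(20, 3.0)]),
                         genes=["a", "neg_a", "const"])
    R, P = net.pairwise_correlation(matrix)
    assert R.loc["a", "a"] == 1.0
    assert R.loc["a", "neg_a"] == pytest.approx(-1.0)
    assert P.loc["a", "neg_a"] == pytest.approx(0.0, abs=1e-12)
    assert R.loc["a", "const"] == 0.0 and P.loc["a", "const"] == 1.0


def test_correlation_pvalue_closed_form():
    # r = 0.5, n = 20 -> t = 2.449, df = 18 -> two-sided p = 0.0248
    p = net._corr_pvalues(np.array(0.5), 20, 18)
    assert float(p) == pytest.approx(0.0248, abs=2e-4)


def test_pairwise_correlation_needs_four_samples():
    with pytest.raises(ValueError, match="4 samples"):
        net.pairwise_correlation(make_matrix(np.ones((2, 3))))


def test_partial_correlation_formula_examples(rng):
    # independent covariate: rp == r_xy
    x = rng.normal(size=500)
    y = 0.5 * x + rng.normal(size=500)
    z = rng.normal(size=500)
    rp, _ = net.partial_correlation(x, y, z)
    r_xy = np.corrcoef(x, y)[0, 1]
    assert rp == pytest.approx(r_xy, abs=0.02)
    # degenerate covariate convention
    rp2, p2 = net.partial_correlation(x, z, z)
    assert rp2 == 0.0 and p2 == 1.0


def test_partial_correlation_fixed_coefficient_arithmetic():
    # (0.6 - 0.5*0.5) / sqrt((1-0.25)(1-0.25)) = 0.35/0.75
    rp = (0.6 - 0.5 * 0.5) / np.sqrt((1 - 0.25) * (1 - 0.25))
    assert rp == pytest.approx(0.4667, abs=1e-4)


def test_partial_correlation_matches_residual_regression_oracle(rng):
    """rp(x, y | z) equals the correlation of OLS residuals of x on z, y on z."""
    for _ in range(100):
        n = rng.integers(6, 40)
        x, y, z = rng.normal(size=(3, n))
        rp, _ = net.partial_correlation(x, y, z)
        Z = np.column_stack([np.ones(n), z])
        rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
        ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert rp == pytest.approx(oracle, abs=1e-10)


def test_partial_correlation_matrix_agrees_with_scalar(rng):
    matrix = make_matrix(rng.normal(size=(6, 30)))
    z = rng.normal(size=30)
    RP, PP = net.partial_correlation_matrix(matrix, z)
    for i, j in itertools.combinations(range(6), 2):
        rp, p = net.partial_correlation(matrix.iloc[i], matrix.iloc[j], z)
        assert RP.iloc[i, j] == pytest.approx(rp, abs=1e-12)
        assert PP.iloc[i, j] == pytest.approx(p, abs=1e-12)


# ---------------------------------------------------------------------------
# BH-FDR
# ---------------------------------------------------------------------------

def test_bh_fdr_hand_computed_step_up():
    assert np.allclose(net.bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)
    # unordered input with a distinct pattern: p = [0.04, 0.01, 0.03]
    # ranks by sorted p: 0.01*3/1=0.03, 0.03*3/2=0.045, 0.04*3/3=0.04 -> monotone min
    assert np.allclose(net.bh_fdr([0.04, 0.01, 0.03]), [0.04, 0.03, 0.04])
    assert net.bh_fdr([0.2]) == pytest.approx([0.2])
    assert net.bh_fdr([1.0]) == pytest.approx([1.0])
    assert net.bh_fdr([]).size == 0


@given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_bh_fdr_q_at_least_p_and_monotone(pvals):
    q = net.bh_fdr(pvals)
    p = np.asarray(pvals)
    assert np.all(q >= p - 1e-12) and np.all(q <= 1.0)
    order = np.argsort(p, kind="stable")
    assert np.all(np.diff(q[order]) >= -1e-12)


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------

def _scored(n, rng):
    return rng.normal(size=n)


def test_identical_groups_give_zero_edges(rng):
    matrix = make_matrix(rng.normal(size=(10, 40)))
    network = net.build_network(matrix, matrix, _scored(40, rng), _scored(40, rng))
    assert network.graph.number_of_edges() == 0


def test_planted_sign_flip_pair_is_retained_with_brute_force_check():
    cfg = syn.SyntheticConfig(
        n_genes=30, n_young=0, n_old_normal=100, n_pd=100,
        n_aging_genes=0, n_pd_genes=0, aging_effect=0.0, pd_effect=0.0,
        n_diff_edges=3, latent_corr_strength=0.8, edge_layout="random",
        masking_latent_sd=0.0, platform_shift_sd=0.0, seed=33,
    )
    matrix, table, truth = syn.generate_cohort(cfg)
    meta = table.set_index("sample_id")
    ctl = [c for c in matrix.columns if meta.loc[c, "group"] == "normal"]
    pdc = [c for c in matrix.columns if meta.loc[c, "group"] == "PD"]
    rng = np.random.default_rng(0)
    zc, zp = rng.normal(size=len(ctl)), rng.normal(size=len(pdc))
    network = net.build_network(matrix[ctl], matrix[pdc], zc, zp)
    assert set(truth.diff_edge_pairs) <= network.edge_set
    # brute-force recomputation of all four coefficients for one planted pair
    g1, g2 = sorted(next(iter(truth.diff_edge_pairs)))
    row = network.edges.set_index(["gene_a", "gene_b"]).loc[(g1, g2)]
    assert row["r_control"] == pytest.approx(
        np.corrcoef(matrix.loc[g1, ctl], matrix.loc[g2, ctl])[0, 1], abs=1e-12)
    assert row["r_pd"] == pytest.approx(
        np.corrcoef(matrix.loc[g1, pdc], matrix.loc[g2, pdc])[0, 1], abs=1e-12)
    rp_c, _ = net.partial_correlation(matrix.loc[g1, ctl], matrix.loc[g2, ctl], zc)
    assert row["rp_control"] == pytest.approx(rp_c, abs=1e-12)
    assert abs(row["r_control"] - row["r_pd"]) > 0.5
    assert abs(row["rp_control"] - row["rp_pd"]) > 0.5


def test_both_delta_conditions_required(rng):
    """A pair differential in plain correlation but not after conditioning is dropped."""
    n = 200
    z = rng.normal(size=n)  # scores drive the control-group correlation
    ctl_g1 = z + 0.3 * rng.normal(size=n)
    ctl_g2 = z + 0.3 * rng.normal(size=n)
    pd_g1, pd_g2 = rng.normal(size=(2, n))
    filler_c, filler_p = rng.normal(size=(2, n)), rng.normal(size=(2, n))
    ctl = make_matrix(np.vstack([ctl_g1, ctl_g2, filler_c]), genes=list("abxy"))
    pdm = make_matrix(np.vstack([pd_g1, pd_g2, filler_p]), genes=list("abxy"))
    network = net.build_network(ctl, pdm, z, rng.normal(size=n))
    # delta_r for (a, b) is ~0.9 but conditioning on z removes the control
    # correlation, so delta_rp is small and the edge must not be retained
    assert frozenset(("a", "b")) not in network.edge_set


def test_network_symmetric_under_group_swap(rng):
    cfg = syn.SyntheticConfig(
        n_genes=40, n_young=0, n_old_normal=80, n_pd=80,
        n_aging_genes=0, n_pd_genes=0, n_diff_edges=4, edge_layout="random",
        masking_latent_sd=0.0, platform_shift_sd=0.0, seed=37,
    )
    matrix, table, _ = syn.generate_cohort(cfg)
    meta = table.set_index("sample_id")
    ctl = [c for c in matrix.columns if meta.loc[c, "group"] == "normal"]
    pdc = [c for c in matrix.columns if meta.loc[c, "group"] == "PD"]
    zc, zp = _scored(len(ctl), rng), _scored(len(pdc), rng)
    n1 = net.build_network(matrix[ctl], matrix[pdc], zc, zp)
    n2 = net.build_network(matrix[pdc], matrix[ctl], zp, zc)
    assert n1.edge_set == n2.edge_set


def test_raising_delta_threshold_never_adds_edges(rng):
    cfg = syn.SyntheticConfig(
        n_genes=40, n_young=0, n_old_normal=60, n_pd=60,
        n_aging_genes=0, n_pd_genes=0, n_diff_edges=6, edge_layout="random",
        latent_corr_strength=0.6, masking_latent_sd=0.0, platform_shift_sd=0.0, seed=41,
    )
    matrix, table, _ = syn.generate_cohort(cfg)
    meta = table.set_index("sample_id")
    ctl = [c for c in matrix.columns if meta.loc[c, "group"] == "normal"]
    pdc = [c for c in matrix.columns if meta.loc[c, "group"] == "PD"]
    zc, zp = _scored(len(ctl), rng), _scored(len(pdc), rng)
    prev = None
    for delta in (0.2, 0.5, 0.8, 1.1):
        edges = net.build_network(matrix[ctl], matrix[pdc], zc, zp,
                                  delta_threshold=delta).edge_set
        if prev is not None:
            assert edges <= prev
        prev = edges


def test_disjoint_universes_error(rng):
    a = make_matrix(rng.normal(size=(3, 10)), genes=["a", "b", "c"])
    b = make_matrix(rng.normal(size=(3, 10)), genes=["x", "y", "z"])
    with pytest.raises(ValueError, match="no genes"):
        net.build_network(a, b, np.zeros(10), np.zeros(10))


# ---------------------------------------------------------------------------
# Fisher similarity
# ---------------------------------------------------------------------------

def _net_from_edges(universe, edges):
    g = nx.Graph(edges)
    frame = pd.DataFrame(edges, columns=["gene_a", "gene_b"])
    return net.DifferentialNetwork(graph=g, edges=frame, universe=list(universe))


def test_fisher_exact_enumeration_example():
    # margins (4,4)/(4,4): p(two-sided) for observed [[3,1],[1,3]] is 34/70
    from scipy.stats import fisher_exact

    _, p = fisher_exact([[3, 1], [1, 3]])
    assert p == pytest.approx(34 / 70, abs=1e-12)


def test_identical_networks_are_detected_similar_against_enumeration():
    universe = [f"G{i}" for i in range(10)]
    edges = [("G0", "G1"), ("G2", "G3"), ("G4", "G5"), ("G6", "G7")]
    a = _net_from_edges(universe, edges)
    b = _net_from_edges(universe, edges)
    odds, p = net.network_similarity_fisher(a, b)
    # oracle: hypergeometric enumeration over C(45,4) pair draws
    total, k = comb(10, 2), len(edges)
    p_match = comb(k, k) * comb(total - k, 0) / comb(total, k)
    assert p <= 1e-4 and p >= p_match  # two-sided sum >= the single extreme table
    disjoint = _net_from_edges(universe, [("G0", "G2"), ("G1", "G3"),
                                          ("G4", "G6"), ("G5", "G7")])
    _, p2 = net.network_similarity_fisher(a, disjoint)
    assert p2 > p


def test_fisher_independent_random_edges_calibrated(rng):
    """Under independent random edge draws the Fisher p-value is ~Uniform."""
    universe = [f"G{i}" for i in range(30)]
    pairs = list(itertools.combinations(universe, 2))
    pvals = []
    for _ in range(200):
        eA = [pairs[i] for i in rng.choice(len(pairs), 60, replace=False)]
        eB = [pairs[i] for i in rng.choice(len(pairs), 60, replace=False)]
        _, p = net.network_similarity_fisher(
            _net_from_edges(universe, eA), _net_from_edges(universe, eB)
        )
        pvals.append(p)
    pvals = np.sort(pvals)
    grid = np.arange(1, 201) / 200
    ks = np.abs(pvals - grid).max()
    assert ks < 0.25  # overlap counts are discrete, so the fit is loose
    assert np.mean(np.asarray(pvals) < 0.05) < 0.12  # not anti-conservative


# ---------------------------------------------------------------------------
# scale-free diagnostic
# ---------------------------------------------------------------------------

def test_star_graph_degenerate():
    star = nx.star_graph(10)
    r, p = net.scale_free_check(star)
    assert np.isnan(r) and np.isnan(p)


def test_preferential_attachment_vs_dense_random():
    ba = nx.barabasi_albert_graph(1000, 2, seed=1)
    r_ba, _ = net.scale_free_check(ba)
    assert r_ba < -0.6
    er = nx.gnp_random_graph(1000, 0.03, seed=1)
    r_er, _ = net.scale_free_check(er)
    assert r_er > -0.3  # near 0 or positive: not scale-free
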