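"""Correlation matrix, density-curve cutoff selection, reciprocal top-k pruning."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drynet.network_build import (
    CorrelationMatrix,
    build_network,
    correlation_matrix,
    degree_stats,
    density_curve_and_cutoff,
    fit_power_law,
)

from conftest import make_expression_set


def pearson_formula(x, y):
    """The textbook sum-form Pearson correlation, |r|."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    num = n * np.sum(x * y) - np.sum(x) * np.sum(y)
    den = math.sqrt(n * np.sum(x**2) - np.sum(x) ** 2) * math.sqrt(
        n * np.sum(y**2) - np.sum(y) ** 2
    )
    return abs(num / den)


def corr_from_matrix(values, genes=None):
    values = np.asarray(values, float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    return CorrelationMatrix(genes=list(genes), values=values, n_samples=10)


class TestCorrelationMatrix:
    def test_identical_and_anticorrelated_profiles_have_r_one(self):
        x = [1.0, 2.0, 3.0, 4.0, 2.5]
        eset = make_expression_set(
            [x[:3], x[:3], [-v for v in x[:3]]],
            [x[3:], x[3:], [-v for v in x[3:]]],
            genes=["a", "b", "c"],
        )
        corr = correlation_matrix([eset])
        assert corr.values[0, 1] == pytest.approx(1.0)
        assert corr.values[0, 2] == pytest.approx(1.0)  # sign folded by |.|

    def test_matches_printed_sum_formula(self):
        x, y = [1, 2, 3, 4], [1.1, 1.9, 3.2, 3.8]
        eset = make_expression_set([x[:2], y[:2]], [x[2:], y[2:]], genes=["a", "b"])
        corr = correlation_matrix([eset])
        assert corr.values[0, 1] == pytest.approx(pearson_formula(x, y), rel=1e-12)

    def test_zero_variance_gene_dropped(self):
        eset = make_expression_set([[1, 2, 3], [5, 5, 5]], [[4, 5, 6], [5, 5, 5]],
                                   genes=["a", "flat"])
        corr = correlation_matrix([eset])
        assert corr.genes == ["a"]

    def test_profiles_concatenate_across_sets(self):
        e1 = make_expression_set([[1, 2, 3], [3, 2, 1]], [[4, 5, 6], [6, 5, 4]],
                                 genes=["a", "b"], set_id="set1")
        e2 = make_expression_set([[2, 2, 4], [4, 2, 2]], [[5, 6, 5], [5, 6, 5]],
                                 genes=["a", "b"], set_id="set2")
        corr = correlation_matrix([e1, e2])
        assert corr.n_samples == 12
        xa = [1, 2, 3, 4, 5, 6, 2, 2, 4, 5, 6, 5]
        xb = [3, 2, 1, 6, 5, 4, 4, 2, 2, 5, 6, 5]
        assert corr.values[0, 1] == pytest.approx(pearson_formula(xa, xb))


class TestDensityCurve:
    def test_selects_interior_minimum(self):
        # block structure: within-block r 0.9/0.8, cross 0.6 +- jitter
        r = np.full((6, 6), 0.6)
        for i, j in [(0, 1), (0, 2), (1, 2)]:
            r[i, j] = r[j, i] = 0.9
        for i, j in [(3, 4), (3, 5), (4, 5)]:
            r[i, j] = r[j, i] = 0.8
        np.fill_diagonal(r, 1.0)
        curve = density_curve_and_cutoff(corr_from_matrix(r), grid=[0.55, 0.65, 0.75, 0.85])
        # at 0.55: E=15,K=6,D=1; 0.65: E=6,K=6,D=0.4; 0.75: E=6,K=6,D=0.4;
        # 0.85: E=3,K=3,D=1 -> argmin ties at 0.65/0.75, smaller cutoff wins
        tab = curve.table.set_index("cutoff")
        assert tab.loc[0.55, ["edges", "nodes"]].tolist() == [15, 6]
        assert tab.loc[0.85, ["edges", "nodes"]].tolist() == [3, 3]
        assert curve.selected_cutoff == 0.65

    def test_strictly_decreasing_curve_selects_last_point_with_warning(self, rng):
        r = rng.uniform(0.0, 1.0, (30, 30))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        with pytest.warns(RuntimeWarning, match="last grid point"):
            curve = density_curve_and_cutoff(corr_from_matrix(r), grid=[0.1, 0.2, 0.3])
        assert curve.selected_cutoff == 0.3

    def test_matches_brute_force_recount_on_random_matrix(self, rng):
        n = 50
        r = rng.uniform(0, 1, (n, n))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        grid = np.round(np.arange(0.50, 0.951, 0.01), 2)
        curve = density_curve_and_cutoff(corr_from_matrix(r), grid=grid)
        for _, row in curve.table.iterrows():
            c = row["cutoff"]
            edges = [
                (i, j) for i, j in itertools.combinations(range(n), 2) if r[i, j] > c
            ]
            nodes = {i for e in edges for i in e}
            assert row["edges"] == len(edges)
            assert row["nodes"] == len(nodes)
            if len(nodes) >= 2:
                poss = len(nodes) * (len(nodes) - 1) / 2
                assert row["density"] == pytest.approx(len(edges) / poss)
            else:
                assert np.isnan(row["density"])


def naive_reciprocal_prune(r, cutoff, k, genes):
    """Independent re-derivation: rank enumeration per node, mutual top-k."""
    n = len(genes)
    adj = {
        (i, j)
        for i, j in itertools.combinations(range(n), 2)
        if r[i, j] > cutoff
    }
    neighbors = {i: set() for i in range(n)}
    for i, j in adj:
        neighbors[i].add(j)
        neighbors[j].add(i)
    topk = {}
    for i in range(n):
        ranked = sorted(neighbors[i], key=lambda j: (-r[i, j], genes[j]))
        topk[i] = set(ranked[:k])
    return {
        tuple(sorted((genes[i], genes[j])))
        for i, j in adj
        if j in topk[i] and i in topk[j]
    }


class TestBuildNetwork:
    def test_chain_with_k1_keeps_only_strongest_mutual_edge(self):
        r = np.eye(3)
        r[0, 1] = r[1, 0] = 0.9
        r[1, 2] = r[2, 1] = 0.8
        net = build_network(corr_from_matrix(r, genes=["a", "b", "c"]),
                           cutoff=0.5, k_limit=1)
        assert set(map(tuple, net.edge_table()[["gene_a", "gene_b"]].values)) == {("a", "b")}

    def test_large_k_limit_leaves_network_unchanged(self, rng):
        r = rng.uniform(0, 1, (12, 12))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        corr = corr_from_matrix(r)
        net = build_network(corr, cutoff=0.5, k_limit=100)
        n_pre = sum(
            1 for i, j in itertools.combinations(range(12), 2) if r[i, j] > 0.5
        )
        assert net.n_edges == n_pre

    def test_auto_k_limit_rounds_half_up_of_mean_degree(self):
        # 4-clique: preliminary average degree 3 -> k_limit 3
        r = np.full((4, 4), 0.9)
        np.fill_diagonal(r, 1.0)
        net = build_network(corr_from_matrix(r), cutoff=0.5, k_limit="auto")
        assert net.k_limit == 3
        # star a-(b,c,d): degrees 3,1,1,1 -> mean 1.5 -> rounds to 2
        r = np.eye(4)
        for j in (1, 2, 3):
            r[0, j] = r[j, 0] = 0.9
        net = build_network(corr_from_matrix(r), cutoff=0.5, k_limit="auto")
        assert net.k_limit == 2

    def test_empty_network_raises(self):
        r = np.eye(3)
        with pytest.raises(ValueError, match="cutoff"):
            build_network(corr_from_matrix(r), cutoff=0.9)

    @pytest.mark.parametrize("k", [1, 3, 10, 10**9])
    def test_matches_naive_rank_enumeration(self, k, rng):
        n = 60
        r = rng.uniform(0, 1, (n, n))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        genes = [f"g{i:03d}" for i in range(n)]
        net = build_network(corr_from_matrix(r, genes=genes), cutoff=0.4,
                           k_limit=min(k, n))
        got = set(map(tuple, net.edge_table()[["gene_a", "gene_b"]].values))
        assert got == naive_reciprocal_prune(r, 0.4, min(k, n), genes)

    def test_pruning_is_order_invariant(self, rng):
        n = 30
        r = rng.uniform(0, 1, (n, n))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        genes = [f"g{i:02d}" for i in range(n)]
        net1 = build_network(corr_from_matrix(r, genes=genes), 0.4, 3)
        perm = rng.permutation(n)
        net2 = build_network(
            corr_from_matrix(r[np.ix_(perm, perm)], genes=[genes[i] for i in perm]),
            0.4, 3,
        )
        assert net1.edge_table().equals(net2.edge_table())


@settings(max_examples=20, deadline=None, derandomize=True)
@given(seed=st.integers(0, 2**20), n=st.integers(5, 30), k=st.integers(1, 8))
def test_pruning_shrinks_and_counts_decrease(seed, n, k):
    """Edge and node counts never increase with the cutoff, and reciprocal
    pruning never adds edges beyond the preliminary thresholded set."""
    rng = np.random.default_rng(seed)
    r = rng.uniform(0, 1, (n, n))
    r = (r + r.T) / 2
    np.fill_diagonal(r, 1.0)
    corr = corr_from_matrix(r)
    curve = density_curve_and_cutoff(corr, grid=[0.2, 0.4, 0.6, 0.8])
    e = curve.table["edges"].to_numpy()
    nodes = curve.table["nodes"].to_numpy()
    assert np.all(np.diff(e) <= 0) and np.all(np.diff(nodes) <= 0)
    prelim = {
        (i, j) for i, j in itertools.combinations(range(n), 2) if r[i, j] > 0.2
    }
    if prelim:
        net = build_network(corr, cutoff=0.2, k_limit=k)
        gene_idx = {g: i for i, g in enumerate(corr.genes)}
        final = {
            tuple(sorted((gene_idx[a], gene_idx[b])))
            for a, b in net.edge_table()[["gene_a", "gene_b"]].values
        }
        assert final <= prelim


class TestDegreeStats:
    def test_power_law_fit_recovers_exponent_on_exact_histogram(self):
        ks = np.arange(1, 11)
        hist = {int(k): int(round(1e6 * k**-2.0)) for k in ks}
        slope, r2 = fit_power_law(hist)
        assert slope == pytest.approx(-2.0, abs=1e-3)
        assert r2 == pytest.approx(1.0, abs=1e-4)

    def test_single_degree_histogram_has_undefined_exponent(self):
        # complete graph: every node has the same degree
        r = np.full((12, 12), 0.9)
        np.fill_diagonal(r, 1.0)
        net = build_network(corr_from_matrix(r), cutoff=0.5, k_limit=20)
        stats = degree_stats(net)
        assert stats.exponent is None
        assert sum(stats.histogram.values()) == net.n_nodes

    def test_histogram_sums_to_node_count(self, rng):
        r = rng.uniform(0.3, 1, (20, 20))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        net = build_network(corr_from_matrix(r), cutoff=0.6, k_limit=5)
        stats = degree_stats(net)
        assert sum(stats.histogram.values()) == net.n_nodes
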