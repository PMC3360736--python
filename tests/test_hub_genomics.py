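"""Intramodular connectivity, hub selection, cluster calling, QTL permutation test."""

import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from drynet.mcl_modules import ModulePartition
from drynet.network_build import CoexpressionNetwork
from drynet.hub_genomics import (
    GenomicTrack,
    count_qtl_overlaps,
    detect_hub_clusters,
    intramodular_connectivity,
    permutation_test,
    select_hubs,
)


def make_net(edges):
    g = nx.Graph()
    for u, v in edges:
        g.add_edge(u, v, weight=0.9)
    return CoexpressionNetwork(graph=g, cutoff=0.71, k_limit=36)


def make_track(rows, qtls=None, chrom_lengths=None):
    genes = pd.DataFrame(
        rows, columns=["gene", "chrom", "start", "end", "connectivity"]
    ).set_index("gene")
    q = (
        pd.DataFrame(qtls, columns=["chrom", "start", "end", "name"])
        if qtls is not None
        else None
    )
    return GenomicTrack(genes=genes, qtls=q, chrom_lengths=chrom_lengths)


class TestIntramodularConnectivity:
    def test_triangle_in_one_module_gives_two_each(self):
        net = make_net([("a", "b"), ("b", "c"), ("a", "c")])
        part = ModulePartition(assignments={"a": 1, "b": 1, "c": 1})
        k = intramodular_connectivity(net, part)
        assert k.tolist() == [2, 2, 2]

    def test_gene_with_only_foreign_neighbors_scores_zero(self):
        net = make_net([("a", "x"), ("a", "y")])
        part = ModulePartition(assignments={"a": 1, "x": 2, "y": 2})
        k = intramodular_connectivity(net, part)
        assert k["a"] == 0  # both neighbors sit in a foreign module
        assert k["x"] == 0 and k["y"] == 0  # x and y are not linked to each other

    def test_matches_brute_force_edge_scan(self, rng):
        g = nx.gnp_random_graph(50, 0.15, seed=5)
        g = nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes})
        nx.set_edge_attributes(g, 0.8, "weight")
        nodes = sorted(g.nodes)
        part = ModulePartition(
            assignments={n: 1 + (i % 4) for i, n in enumerate(nodes)}
        )
        k = intramodular_connectivity(
            CoexpressionNetwork(graph=g, cutoff=0.7, k_limit=36), part
        )
        for n in nodes:
            expected = sum(
                1 for nb in g.neighbors(n)
                if part.assignments[nb] == part.assignments[n]
            )
            assert k[n] == expected


class TestSelectHubs:
    @pytest.mark.parametrize(
        "size,expected", [(10, 2), (21, 5), (134, 27), (303, 61)]
    )
    def test_ceil_of_top_fraction_per_module(self, size, expected):
        part = ModulePartition(assignments={f"g{i:03d}": 1 for i in range(size)})
        k = pd.Series(np.arange(size), index=[f"g{i:03d}" for i in range(size)])
        hubs = select_hubs(part, k, fraction=0.20)
        assert len(hubs) == expected
        # highest-connectivity genes selected
        assert f"g{size - 1:03d}" in hubs

    def test_connectivity_ties_break_by_gene_id(self):
        part = ModulePartition(assignments={g: 1 for g in "abcde"})
        k = pd.Series(1.0, index=list("abcde"))
        assert select_hubs(part, k, fraction=0.2) == ["a"]


class TestDetectHubClusters:
    def test_span_exactly_at_limit_is_rejected(self):
        # two genes 0.5 Mb apart in one bin: score 110 > 100 but span not > 0.5 Mb
        track = make_track(
            [("a", "chr1", 200_000, 205_000, 60.0),
             ("b", "chr1", 700_000, 705_000, 50.0)]
        )
        assert len(detect_hub_clusters(track)) == 0

    def test_sufficient_span_yields_one_cluster(self):
        track = make_track(
            [("a", "chr1", 100_000, 105_000, 80.0),
             ("b", "chr1", 800_000, 805_000, 40.0)]
        )
        cl = detect_hub_clusters(track)
        assert len(cl) == 1
        row = cl.iloc[0]
        assert row["score"] == pytest.approx(120.0)
        assert row["span"] == 700_000
        assert (row["start"], row["end"]) == (100_000, 805_000)
        assert row["genes"] == ["a", "b"]

    def test_adjacent_passing_bins_merge(self):
        track = make_track(
            [("a", "chr1", 900_000, 905_000, 120.0),
             ("b", "chr1", 1_500_000, 1_505_000, 130.0)]
        )
        cl = detect_hub_clusters(track)
        assert len(cl) == 1
        assert cl.iloc[0]["score"] == pytest.approx(250.0)
        assert cl.iloc[0]["span"] == 600_000

    def test_bins_separated_by_a_gap_stay_separate(self):
        track = make_track(
            [("a1", "chr1", 100_000, 101_000, 80.0),
             ("a2", "chr1", 900_000, 901_000, 80.0),
             ("b1", "chr1", 5_100_000, 5_101_000, 80.0),
             ("b2", "chr1", 5_900_000, 5_901_000, 80.0)]
        )
        assert len(detect_hub_clusters(track)) == 2

    def test_chromosome_boundary_breaks_runs(self):
        # same global bin arithmetic, different chromosomes: never one cluster
        track = make_track(
            [("a", "chr1", 100_000, 101_000, 150.0),
             ("b", "chr1", 900_000, 901_000, 10.0),
             ("c", "chr2", 100_000, 101_000, 150.0),
             ("d", "chr2", 900_000, 901_000, 10.0)]
        )
        cl = detect_hub_clusters(track)
        assert len(cl) == 2
        assert set(cl["chrom"]) == {"chr1", "chr2"}

    def test_empty_chromosome_yields_no_clusters(self):
        track = make_track([("a", "chr3", 100_000, 101_000, 5.0)])
        assert len(detect_hub_clusters(track)) == 0

    def test_gene_beyond_declared_length_rejected(self):
        track = make_track(
            [("a", "chr1", 100_000, 101_000, 5.0)],
            chrom_lengths={"chr1": 100_500},
        )
        with pytest.raises(ValueError, match="beyond declared length"):
            detect_hub_clusters(track)

    def test_bin_scores_conserve_total_connectivity(self, rng):
        rows = [
            (f"g{i}", f"chr{rng.integers(1, 4)}", int(s), int(s) + 1000, float(k))
            for i, (s, k) in enumerate(
                zip(rng.integers(0, 10_000_000, 200), rng.integers(0, 40, 200))
            )
        ]
        track = make_track(rows)
        from drynet.hub_genomics import _BinnedTrack

        bt = _BinnedTrack(track, 1_000_000)
        pos = bt.k > 0
        scores = np.bincount(bt.bin_index[pos], weights=bt.k[pos],
                             minlength=bt.n_bins)
        assert scores.sum() == pytest.approx(track.genes["connectivity"].sum())

    def test_invariant_to_gene_input_order(self, rng):
        rows = [
            (f"g{i}", "chr1", int(s), int(s) + 1000, float(k))
            for i, (s, k) in enumerate(
                zip(rng.integers(0, 8_000_000, 60), rng.integers(10, 60, 60))
            )
        ]
        cl1 = detect_hub_clusters(make_track(rows))
        cl2 = detect_hub_clusters(make_track(rows[::-1]))
        pd.testing.assert_frame_equal(cl1, cl2)


class TestCountQTLOverlaps:
    def test_partial_overlap_counts(self):
        cl = pd.DataFrame([("chr1", 1_000_000, 2_000_000)],
                          columns=["chrom", "start", "end"])
        q = pd.DataFrame([("chr1", 1_500_000, 3_000_000, "q1")],
                         columns=["chrom", "start", "end", "name"])
        assert count_qtl_overlaps(cl, q) == 1

    def test_half_open_touching_does_not_overlap(self):
        cl = pd.DataFrame([("chr1", 1_000_000, 2_000_000)],
                          columns=["chrom", "start", "end"])
        q = pd.DataFrame([("chr1", 2_000_000, 3_000_000, "q1")],
                         columns=["chrom", "start", "end", "name"])
        assert count_qtl_overlaps(cl, q) == 0

    def test_counts_clusters_not_qtls(self):
        cl = pd.DataFrame(
            [("chr1", 0, 1_000_000), ("chr1", 5_000_000, 6_000_000),
             ("chr2", 0, 1_000_000)],
            columns=["chrom", "start", "end"],
        )
        q = pd.DataFrame(
            [("chr1", 500_000, 5_500_000, "q1"), ("chr2", 2_000_000, 3_000_000, "q2")],
            columns=["chrom", "start", "end", "name"],
        )
        # exhaustive pair scan: clusters 1 and 2 hit q1, cluster 3 hits nothing
        assert count_qtl_overlaps(cl, q) == 2

    def test_chromosome_naming_mismatch_raises(self):
        cl = pd.DataFrame([("chr1", 0, 1_000_000)], columns=["chrom", "start", "end"])
        q = pd.DataFrame([("1", 0, 1_000_000, "q1")],
                         columns=["chrom", "start", "end", "name"])
        with pytest.raises(ValueError, match="naming mismatch"):
            count_qtl_overlaps(cl, q)


class TestPermutationTest:
    @staticmethod
    def _random_track(rng, n=300):
        rows = [
            (f"g{i:03d}", f"chr{rng.integers(1, 6)}", int(s), int(s) + 2000, float(k))
            for i, (s, k) in enumerate(
                zip(rng.integers(0, 20_000_000, n),
                    rng.choice([0, 2, 5, 30, 36], size=n, p=[0.2, 0.3, 0.3, 0.1, 0.1]))
            )
        ]
        qtls = [
            (f"chr{rng.integers(1, 6)}", int(s), int(s) + 3_000_000, f"q{j}")
            for j, s in enumerate(rng.integers(0, 17_000_000, 10))
        ]
        return make_track(rows, qtls=qtls)

    def test_p_equals_exceedance_fraction(self, rng):
        track = self._random_track(rng)
        res = permutation_test(track, n_perm=250, seed=1)
        assert res.p_value == (res.null_counts > res.actual).sum() / 250
        assert res.null_counts.shape == (250,)

    def test_seed_reproducibility(self, rng):
        track = self._random_track(rng)
        r1 = permutation_test(track, n_perm=100, seed=42)
        r2 = permutation_test(track, n_perm=100, seed=42)
        assert np.array_equal(r1.null_counts, r2.null_counts)
        assert r1.p_value == r2.p_value

    def test_plus_one_correction(self, rng):
        track = self._random_track(rng)
        r = permutation_test(track, n_perm=100, seed=7, plus_one=True)
        exceed = int((r.null_counts > r.actual).sum())
        assert r.p_value == pytest.approx((exceed + 1) / 101)

    def test_zero_exceedances_formats_as_bound(self, rng):
        track = make_track(
            [(f"g{i}", "chr1", int(100_000 + i * 180_000), int(101_000 + i * 180_000),
              40.0) for i in range(5)]
            + [(f"h{i}", "chr2", int(100_000 + i * 37_000), int(101_000 + i * 37_000),
                0.0) for i in range(40)],
            qtls=[("chr1", 0, 2_000_000, "q1")],
        )
        res = permutation_test(track, n_perm=200, seed=3)
        if res.p_value == 0:
            assert res.format_p() == "< 0.005"

    def test_actual_count_matches_direct_computation(self, rng):
        track = self._random_track(rng)
        res = permutation_test(track, n_perm=10, seed=0)
        clusters = detect_hub_clusters(track)
        assert res.actual == count_qtl_overlaps(clusters, track.qtls)
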