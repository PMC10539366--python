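"""Regulatory network assembly, FFL enumeration, stats and ranking."""

import itertools

import numpy as np
import pandas as pd
import pytest

from immffl.errors import ClassConflictError
from immffl.ffl import (
    MIRNA_MRNA,
    MIRNA_TF,
    TF_MRNA,
    FFLMotif,
    RegulatoryEdgeSet,
    build_regulatory_network,
    enumerate_ffls,
    network_stats,
    rank_motifs,
)


def edges_df(rows):
    return pd.DataFrame(rows, columns=["source", "target", "type"])


def brute_force_ffls(edges):
    """O(M*T*G) triple loop over all candidate (mirna, tf, mrna) triples."""
    es = set(map(tuple, edges))
    mirnas = {s for s, _, t in es if t in (MIRNA_MRNA, MIRNA_TF)}
    tfs = {s for s, _, t in es if t == TF_MRNA} | {
        d for _, d, t in es if t == MIRNA_TF
    }
    mrnas = {d for _, d, t in es if t in (TF_MRNA, MIRNA_MRNA)}
    out = []
    for m in sorted(mirnas):
        for t in sorted(tfs):
            for g in sorted(mrnas):
                if (
                    (m, g, MIRNA_MRNA) in es
                    and (m, t, MIRNA_TF) in es
                    and (t, g, TF_MRNA) in es
                ):
                    out.append((m, t, g))
    return out


def random_tripartite(rng, n_per_class=5, p=0.5):
    mirnas = [f"m{i}" for i in range(n_per_class)]
    tfs = [f"t{i}" for i in range(n_per_class)]
    mrnas = [f"g{i}" for i in range(n_per_class)]
    rows = []
    for m, g in itertools.product(mirnas, mrnas):
        if rng.random() < p:
            rows.append((m, g, MIRNA_MRNA))
    for m, t in itertools.product(mirnas, tfs):
        if rng.random() < p:
            rows.append((m, t, MIRNA_TF))
    for t, g in itertools.product(tfs, mrnas):
        if rng.random() < p:
            rows.append((t, g, TF_MRNA))
    return rows


class TestBuildNetwork:
    def _tables(self):
        tf_table = pd.DataFrame(
            {
                "tf": ["t1", "t1", "t2", "t3"],
                "target": ["g1", "g2", "g1", "g9"],
                "p": [1e-5, 0.001, 0.05, 1e-6],
            }
        )
        mirna_edges = edges_df(
            [
                ("m1", "g1", MIRNA_MRNA),
                ("m1", "t1", MIRNA_TF),
                ("m2", "g1", MIRNA_MRNA),
                ("m9", "g1", MIRNA_MRNA),  # not a DEM
                ("m1", "t2", MIRNA_TF),  # t2 not retained (p > cutoff)
            ]
        )
        return tf_table, mirna_edges

    def test_empty_dems_drop_all_mirna_edges(self):
        tf_table, mirna_edges = self._tables()
        net = build_regulatory_network(["g1", "g2"], tf_table, mirna_edges, [])
        assert (net.edges["type"] == TF_MRNA).all()

    def test_tf_p_cutoff_is_inclusive(self):
        tf_table, mirna_edges = self._tables()
        net = build_regulatory_network(["g1", "g2"], tf_table, mirna_edges, ["m1", "m2"])
        kept = set(
            map(tuple, net.edges[net.edges["type"] == TF_MRNA][["source", "target"]].itertuples(index=False))
        )
        assert ("t1", "g2") in kept  # p == 0.001 retained
        assert ("t2", "g1") not in kept  # p = 0.05 dropped
        assert ("t3", "g9") not in kept  # non-hub target dropped

    def test_non_dem_and_non_retained_targets_filtered(self):
        tf_table, mirna_edges = self._tables()
        net = build_regulatory_network(["g1", "g2"], tf_table, mirna_edges, ["m1", "m2"])
        pairs = set(map(tuple, net.edges[["source", "target"]].itertuples(index=False)))
        assert ("m9", "g1") not in pairs
        assert ("m1", "t2") not in pairs

    def test_class_conflict_detected(self):
        rows = edges_df([("x", "g1", MIRNA_MRNA), ("x", "g1", TF_MRNA)])
        with pytest.raises(ClassConflictError):
            RegulatoryEdgeSet(rows)


class TestEnumerate:
    def test_single_closed_triple(self):
        net = RegulatoryEdgeSet(
            edges_df(
                [("m1", "g1", MIRNA_MRNA), ("m1", "t1", MIRNA_TF), ("t1", "g1", TF_MRNA)]
            )
        )
        assert [m.key for m in enumerate_ffls(net)] == [("m1", "t1", "g1")]

    def test_missing_tf_mrna_edge_closes_nothing(self):
        net = RegulatoryEdgeSet(
            edges_df([("m1", "g1", MIRNA_MRNA), ("m1", "t1", MIRNA_TF)])
        )
        assert enumerate_ffls(net) == []

    def test_matches_brute_force_on_random_networks(self):
        rng = np.random.default_rng(10)
        for _ in range(100):
            rows = random_tripartite(rng, n_per_class=int(rng.integers(2, 7)))
            if not rows:
                continue
            net = RegulatoryEdgeSet(edges_df(rows))
            assert [m.key for m in enumerate_ffls(net)] == brute_force_ffls(rows)

    def test_motif_count_monotone_under_edge_addition(self):
        rng = np.random.default_rng(11)
        rows = random_tripartite(rng, n_per_class=4, p=0.3)
        rows_more = rows + [
            r for r in random_tripartite(rng, n_per_class=4, p=0.3) if r not in rows
        ]
        n1 = len(enumerate_ffls(RegulatoryEdgeSet(edges_df(rows))))
        n2 = len(enumerate_ffls(RegulatoryEdgeSet(edges_df(rows_more))))
        assert n2 >= n1


def published_style_rows():
    """7 miRNAs, 5 TFs, 4 mRNAs wired round-robin into 12 TF->mRNA,
    10 miRNA->mRNA and 15 miRNA->TF distinct edges covering every node."""
    mirnas = [f"m{i}" for i in range(7)]
    tfs = [f"t{i}" for i in range(5)]
    mrnas = [f"g{i}" for i in range(4)]
    rows = [(tfs[i % 5], mrnas[i % 4], TF_MRNA) for i in range(12)]
    rows += [(mirnas[i % 7], mrnas[i % 4], MIRNA_MRNA) for i in range(10)]
    rows += [(mirnas[i % 7], tfs[i % 5], MIRNA_TF) for i in range(15)]
    return rows


class TestNetworkStats:
    def test_published_style_totals(self):
        # per-type edge counts (12, 10, 15) over class sizes (7, 4, 5)
        # must total 16 nodes / 37 edges
        stats = network_stats(RegulatoryEdgeSet(edges_df(published_style_rows())))
        assert (stats.n_edges_tf_mrna, stats.n_edges_mirna_mrna, stats.n_edges_mirna_tf) == (12, 10, 15)
        assert (stats.n_mirnas, stats.n_mrnas, stats.n_tfs) == (7, 4, 5)
        assert stats.total_edges == 37
        assert stats.total_nodes == 16

    def test_single_motif_degrees_all_two(self):
        net = RegulatoryEdgeSet(
            edges_df(
                [("m1", "g1", MIRNA_MRNA), ("m1", "t1", MIRNA_TF), ("t1", "g1", TF_MRNA)]
            )
        )
        stats = network_stats(net)
        assert stats.degree_range == {
            "mirna": (2, 2), "tf": (2, 2), "mrna": (2, 2),
        }
        assert stats.avg_degree == {"mirna": 2.0, "tf": 2.0, "mrna": 2.0}

    def test_sum_identities_on_random_networks(self):
        rng = np.random.default_rng(14)
        for _ in range(25):
            rows = random_tripartite(rng, n_per_class=int(rng.integers(2, 8)), p=0.4)
            if not rows:
                continue
            stats = network_stats(RegulatoryEdgeSet(edges_df(rows)))
            assert stats.total_edges == (
                stats.n_edges_tf_mrna + stats.n_edges_mirna_mrna + stats.n_edges_mirna_tf
            )
            assert stats.total_nodes == stats.n_mirnas + stats.n_tfs + stats.n_mrnas


class TestRanking:
    def test_single_motif_is_rank_one(self):
        net = RegulatoryEdgeSet(
            edges_df(
                [("m1", "g1", MIRNA_MRNA), ("m1", "t1", MIRNA_TF), ("t1", "g1", TF_MRNA)]
            )
        )
        ranked = rank_motifs(enumerate_ffls(net), net)
        assert ranked[0].key == ("m1", "t1", "g1")
        assert ranked[0].degree_sum == 6

    def test_extra_edges_promote_a_motif(self):
        rows = [
            ("m1", "g1", MIRNA_MRNA), ("m1", "t1", MIRNA_TF), ("t1", "g1", TF_MRNA),
            ("m2", "g2", MIRNA_MRNA), ("m2", "t2", MIRNA_TF), ("t2", "g2", TF_MRNA),
            # boost m2's triple
            ("m3", "t2", MIRNA_TF), ("m4", "t2", MIRNA_TF), ("m5", "g2", MIRNA_MRNA),
        ]
        net = RegulatoryEdgeSet(edges_df(rows))
        ranked = rank_motifs(enumerate_ffls(net), net)
        assert ranked[0].key == ("m2", "t2", "g2")

    def test_family_filter_restricts_candidates(self):
        rows = [
            ("m1", "g1", MIRNA_MRNA), ("m1", "t1", MIRNA_TF), ("t1", "g1", TF_MRNA),
            ("m2", "g2", MIRNA_MRNA), ("m2", "t2", MIRNA_TF), ("t2", "g2", TF_MRNA),
        ]
        net = RegulatoryEdgeSet(edges_df(rows))
        ranked = rank_motifs(enumerate_ffls(net), net, family=["m2"])
        assert [m.mirna_id for m in ranked] == ["m2"]

    def test_ranking_stable_across_input_permutations(self):
        rng = np.random.default_rng(15)
        rows = random_tripartite(rng, n_per_class=6, p=0.5)
        net = RegulatoryEdgeSet(edges_df(rows))
        motifs = enumerate_ffls(net)
        shuffled = list(motifs)
        rng.shuffle(shuffled)
        assert rank_motifs(motifs, net) == rank_motifs(shuffled, net)
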