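import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metalith.diffstats import DifferentialResult
from metalith.netmap import (
    Fingerprint,
    MetaboliteNetwork,
    NetworkError,
    map_statistics,
    merge_networks,
    read_sif,
    rpair_edges,
    similarity_edges,
    tanimoto,
    write_node_attributes,
    write_sif,
)
from metalith.study_io import ReactionPairTable
from metalith.synthetic import generate_compounds

fp = Fingerprint.from_string


class TestTanimoto:
    def test_identical_nonzero(self):
        assert tanimoto(fp("1100"), fp("1100")) == 1.0

    def test_disjoint(self):
        assert tanimoto(fp("1100"), fp("0011")) == 0.0

    def test_hand_count(self):
        # intersection {bit0}, union {bit0, bit1, bit2} -> 1/3
        assert tanimoto(fp("1100"), fp("1010")) == pytest.approx(1 / 3)

    def test_both_empty_is_zero_by_convention(self):
        assert tanimoto(fp("0000"), fp("0000")) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(NetworkError):
            tanimoto(fp("10"), fp("100"))

    @settings(max_examples=200, derandomize=True)
    @given(st.lists(st.booleans(), min_size=8, max_size=8),
           st.lists(st.booleans(), min_size=8, max_size=8))
    def test_symmetric_and_bounded(self, a, b):
        x, y = Fingerprint.from_bits(a), Fingerprint.from_bits(b)
        s = tanimoto(x, y)
        assert 0.0 <= s <= 1.0
        assert s == tanimoto(y, x)


def three_node_fps():
    """Pairwise similarities: (a,b)=0.9+, (a,c)=(b,c) small but nonzero."""
    a = fp("1111111110")
    b = fp("1111111100")  # tanimoto(a,b) = 8/9
    c = fp("1100000001")  # low overlap with both
    return {"a": a, "b": b, "c": c}


class TestSimilarityEdges:
    def test_isolated_node_gets_one_fallback(self):
        fps = three_node_fps()
        sims = {
            (x, y): tanimoto(fps[x], fps[y])
            for x, y in itertools.combinations(sorted(fps), 2)
        }
        assert sims[("a", "b")] > 0.5
        assert sims[("a", "c")] < 0.5 and sims[("b", "c")] < 0.5
        edges = similarity_edges(fps, threshold=0.5)
        sim_edges = {e for e in edges if e[2] == "similarity"}
        fb_edges = {e for e in edges if e[2] == "similarity_fallback"}
        assert sim_edges == {("a", "b", "similarity")}
        assert len(fb_edges) == 1
        (x, y, _), = fb_edges
        assert "c" in (x, y)
        # fallback goes to c's most similar neighbor
        best = max(("a", "b"), key=lambda o: sims[tuple(sorted((o, "c")))])
        assert {x, y} == {"c", best}

    def test_all_above_threshold_no_fallbacks(self):
        fps = {"a": fp("11110"), "b": fp("11100"), "c": fp("11111")}
        edges = similarity_edges(fps, threshold=0.5)
        assert all(e[2] == "similarity" for e in edges)
        assert len(edges) == 3

    def test_every_node_connected_when_similarity_positive(self):
        rng = np.random.default_rng(20)
        for trial in range(5):
            fps = {
                f"n{i}": Fingerprint.from_bits(rng.integers(0, 2, 24))
                for i in range(8)
            }
            edges = similarity_edges(fps, threshold=0.5)
            touched = {x for a, b, _ in edges for x in (a, b)}
            for node in fps:
                best = max(
                    tanimoto(fps[node], fps[o]) for o in fps if o != node
                )
                if best > 0:
                    assert node in touched

    def test_invariant_to_input_order(self):
        fps = three_node_fps()
        e1 = similarity_edges(dict(sorted(fps.items())))
        e2 = similarity_edges(dict(sorted(fps.items(), reverse=True)))
        assert e1 == e2

    def test_single_node_warns_empty(self):
        with pytest.warns(UserWarning):
            assert similarity_edges({"a": fp("1010")}) == set()

    def test_reciprocal_fallbacks_deduplicated(self):
        # two dissimilar-but-nonzero nodes: each falls back to the other
        fps = {"a": fp("110000"), "b": fp("100011")}
        edges = similarity_edges(fps, threshold=0.5)
        assert edges == {("a", "b", "similarity_fallback")}


class TestRpairEdges:
    def test_resolvable_pair_becomes_edge(self):
        # ascorbate -> threonate style oxidative-cleavage pair
        rp = ReactionPairTable(pairs=[("C00072", "C01620", "main")])
        resolver = {"C00072": "ascorbic_acid", "C01620": "threonic_acid"}
        edges, report = rpair_edges(
            ["ascorbic_acid", "threonic_acid"], rp, resolver
        )
        assert edges == {("ascorbic_acid", "threonic_acid", "rpair")}
        assert report["n_unresolved"] == 0

    def test_absent_compound_counted_not_fatal(self):
        rp = ReactionPairTable(pairs=[("A", "B", "main"), ("A", "Z", "main")])
        edges, report = rpair_edges(["a", "b"], rp, {"A": "a", "B": "b"})
        assert edges == {("a", "b", "rpair")}
        assert report["n_unresolved"] == 1

    def test_planted_pairs_all_recovered(self):
        from metalith.synthetic import generate_rpairs

        ids = [f"M{i + 1:04d}" for i in range(10)]
        table, planted = generate_rpairs(ids, k=4, seed=3)
        edges, report = rpair_edges(ids, table, {i: i for i in ids})
        assert len(edges) == 4
        assert {(a, b) for a, b, _ in edges} == {
            tuple(sorted(p)) for p in planted
        }


class TestMergeNetworks:
    def test_disjoint_edge_sets_union(self):
        nodes = list("abcdefgh")
        sim = {("a", "b", "similarity"), ("c", "d", "similarity"),
               ("e", "f", "similarity_fallback")}
        rxn = {("a", "c", "rpair"), ("b", "d", "rpair"), ("e", "g", "rpair"),
               ("f", "h", "rpair")}
        net = merge_networks(sim, rxn, nodes)
        assert net.n_edges == 7
        assert net.n_nodes == 8

    def test_same_pair_keeps_both_types(self):
        sim = {("a", "b", "similarity")}
        rxn = {("a", "b", "rpair")}
        net = merge_networks(sim, rxn, ["a", "b"])
        assert net.n_edges == 2
        assert {e[2] for e in net.edges} == {"similarity", "rpair"}

    def test_dangling_endpoint_rejected(self):
        with pytest.raises(NetworkError, match="z"):
            merge_networks({("a", "z", "similarity")}, set(), ["a"])

    def test_node_union_property_random_graphs(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            nodes = [f"n{i}" for i in range(rng.integers(3, 10))]
            def rand_edges(etype, k):
                out = set()
                for _ in range(k):
                    a, b = rng.choice(nodes, 2, replace=False)
                    out.add((min(a, b), max(a, b), etype))
                return out
            sim = rand_edges("similarity", rng.integers(0, 6))
            rxn = rand_edges("rpair", rng.integers(0, 6))
            net = merge_networks(sim, rxn, nodes)
            assert set(net.nodes) == set(nodes)
            assert net.n_edges <= len(sim) + len(rxn)


def make_result(mid, ratio, p):
    return DifferentialResult(
        metabolite_id=mid, name=mid, stratum={"tissue": "cerebellum"},
        contrast=({"treatment": "lithium"}, {"treatment": "control"}),
        n_num=11, n_den=10, mean_num=ratio, sd_num=0.1, mean_den=1.0,
        sd_den=0.1, ratio=ratio, F=1.0, p=p,
    )


class TestMapStatistics:
    def net(self, nodes=("a", "b", "c")):
        return merge_networks(set(), set(), nodes)

    def test_null_node_neutral_minimum(self):
        out = map_statistics(self.net(), [make_result("a", 1.0, 1.0)])
        attrs = out.nodes["a"]
        assert attrs["direction"] == "neutral"
        assert attrs["size"] == 20.0
        assert attrs["intensity"] == 0

    def test_large_published_effect_saturates(self):
        # 10.6-fold at p=0.002: |log2| = 3.41 clips at the cap, p in the <0.01 band
        out = map_statistics(self.net(), [make_result("a", 10.6, 0.002)])
        attrs = out.nodes["a"]
        assert attrs["size"] == 80.0
        assert attrs["direction"] == "up"
        assert attrs["intensity"] == 2

    def test_reciprocal_ratios_equal_size_opposite_direction(self):
        out = map_statistics(
            self.net(), [make_result("a", 2.5, 0.03), make_result("b", 0.4, 0.03)]
        )
        assert out.nodes["a"]["size"] == pytest.approx(out.nodes["b"]["size"])
        assert out.nodes["a"]["direction"] == "up"
        assert out.nodes["b"]["direction"] == "down"

    def test_unmapped_node_stays_neutral(self):
        out = map_statistics(self.net(), [make_result("a", 2.0, 0.01)])
        assert out.nodes["c"]["direction"] == "neutral"
        assert out.nodes["c"]["size"] == 20.0

    @pytest.mark.parametrize(
        "p,level", [(0.0005, 3), (0.005, 2), (0.03, 1), (0.2, 0), (1.0, 0)]
    )
    def test_intensity_bands(self, p, level):
        out = map_statistics(self.net(), [make_result("a", 2.0, p)])
        assert out.nodes["a"]["intensity"] == level

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(NetworkError):
            map_statistics(self.net(), [make_result("a", -1.0, 0.5)])


class TestSifExport:
    def test_sorted_lines(self, tmp_path):
        net = merge_networks(
            {("b", "c", "similarity")}, {("a", "b", "rpair")}, ["a", "b", "c"]
        )
        p = tmp_path / "n.sif"
        write_sif(net, p)
        assert p.read_text().splitlines() == [
            "a\trpair\tb",
            "b\tsimilarity\tc",
        ]

    def test_round_trip_edge_multiset(self, tmp_path):
        fps, _ = generate_compounds(12, fp_length=128, n_clusters=3, seed=9,
                                    core_bits=20, noise_bits=6)
        edges = similarity_edges(fps)
        net = merge_networks(edges, set(), list(fps))
        p = tmp_path / "n.sif"
        write_sif(net, p)
        assert read_sif(p) == net.edges

    def test_empty_network_empty_file(self, tmp_path):
        net = MetaboliteNetwork(nodes={"a": {}}, edges=set())
        p = tmp_path / "n.sif"
        write_sif(net, p)
        assert p.read_text() == ""

    def test_node_attributes_export(self, tmp_path):
        net = map_statistics(
            merge_networks(set(), set(), ["a", "b"]),
            [make_result("a", 2.0, 0.004)],
        )
        p = tmp_path / "attrs.tsv"
        write_node_attributes(net, p)
        lines = p.read_text().splitlines()
        assert lines[0].split("\t") == ["id", "size", "direction", "intensity",
                                        "ratio", "p"]
        row_a = dict(zip(lines[0].split("\t"), lines[1].split("\t")))
        assert row_a["direction"] == "up" and row_a["intensity"] == "2"


class TestGeneratedClusters:
    def test_cluster_structure_in_similarity_layer(self):
        fps, labels = generate_compounds(10, fp_length=256, n_clusters=2,
                                         seed=4, core_bits=40, noise_bits=8)
        edges = similarity_edges(fps, threshold=0.5)
        for a, b, etype in edges:
            if etype == "similarity":
                assert labels[a] == labels[b]  # no cross-cluster hard edges

    def test_two_compounds_one_cluster_single_edge(self):
        fps, _ = generate_compounds(2, fp_length=128, n_clusters=1, seed=5,
                                    core_bits=30, noise_bits=5)
        edges = similarity_edges(fps)
        assert len(edges) == 1 and next(iter(edges))[2] == "similarity"
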