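from itertools import product

import networkx as nx
import pytest

from pinemap.cos import (
    CosFlags,
    ValidationError,
    align_linkage_groups,
    categorize_cos,
    categorize_one,
    filter_cos_hits,
    hits_to_graph,
    identify_cos,
    identify_singletons,
    mcl_cluster,
)
from pinemap.formats import SimilarityHit
from pinemap.simulate import simulate_cos_universe


def hit(q, s, ident=95.0, alen=450, qlen=500, slen=500):
    return SimilarityHit(q, s, ident, alen, qlen, slen)


class TestHitFilter:
    def test_passing_hit_kept(self):
        assert filter_cos_hits([hit("a", "b", 95.0, alen=375)]) == [
            hit("a", "b", 95.0, alen=375)
        ]

    def test_low_coverage_removed(self):
        assert filter_cos_hits([hit("a", "b", 95.0, alen=275)]) == []  # 0.55

    def test_identity_boundary_removed(self):
        assert filter_cos_hits([hit("a", "b", 80.0)]) == []

    def test_self_hits_removed(self):
        assert filter_cos_hits([hit("a", "a")]) == []

    def test_coverage_uses_shorter_sequence(self):
        h = hit("a", "b", 95.0, alen=310, qlen=500, slen=400)
        assert filter_cos_hits([h]) == [h]  # 310/400 = 0.775

    def test_idempotent(self):
        hits = [hit("a", "b"), hit("a", "c", 70.0), hit("b", "c", 95.0, alen=100)]
        once = filter_cos_hits(hits)
        assert filter_cos_hits(once) == once


class TestMcl:
    def clique(self, g, names, w=1.0):
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                g.add_edge(a, b, weight=w)

    def test_disjoint_triangles_never_merge(self):
        g = nx.Graph()
        self.clique(g, ["a", "b", "c"])
        self.clique(g, ["x", "y", "z"])
        assert sorted(mcl_cluster(g), key=min) == [{"a", "b", "c"}, {"x", "y", "z"}]

    def test_isolated_node_is_singleton(self):
        g = nx.Graph()
        g.add_node("solo")
        g.add_edge("a", "b", weight=1.0)
        assert {"solo"} in mcl_cluster(g)

    def test_barbell_splits_at_weak_edge(self):
        g = nx.Graph()
        self.clique(g, ["a0", "a1", "a2", "a3"], 1.0)
        self.clique(g, ["b0", "b1", "b2", "b3"], 1.0)
        g.add_edge("a0", "b0", weight=0.1)
        clusters = sorted(mcl_cluster(g), key=min)
        assert clusters == [{"a0", "a1", "a2", "a3"}, {"b0", "b1", "b2", "b3"}]

    def test_output_is_partition(self):
        pine, spruce, within, cross, _ = simulate_cos_universe(seed=2)
        g = hits_to_graph(filter_cos_hits(within + cross), all_ids=pine + spruce)
        clusters = mcl_cluster(g)
        members = [m for c in clusters for m in c]
        assert sorted(members) == sorted(set(members)) == sorted(pine + spruce)

    def test_nonfinite_weight_rejected(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=float("nan"))
        with pytest.raises(ValueError):
            mcl_cluster(g)


class TestSingletonsAndCos:
    def test_singletons_from_cluster_sizes(self):
        clusters = [{"a", "b", "c"}, {"d"}, {"e"}]
        assert identify_singletons({"a", "b", "c", "d", "e"}, clusters) == {"d", "e"}

    def test_fully_connected_no_singletons(self):
        assert identify_singletons({"a", "b"}, [{"a", "b"}]) == set()

    def test_pair_family_is_cos(self):
        fams = identify_cos({"p1"}, {"s1"}, [{"p1", "s1"}])
        assert fams[0].is_cos

    def test_triple_family_not_cos(self):
        fams = identify_cos({"p1", "p2"}, {"s1"}, [{"p1", "p2", "s1"}])
        assert not fams[0].is_cos

    def test_planted_orthologs_recovered_exactly(self):
        pine, spruce, within, cross, truth = simulate_cos_universe(
            seed=5, n_orthologs=10, n_paralog_families=3
        )
        wf = filter_cos_hits(within)
        clusters = mcl_cluster(hits_to_graph(wf, all_ids=pine + spruce))
        ps = identify_singletons(pine, clusters)
        ss = identify_singletons(spruce, clusters)
        joined = ps | ss
        cf = [
            h
            for h in filter_cos_hits(cross)
            if h.query_id in joined and h.subject_id in joined
        ]
        fams = identify_cos(ps, ss, mcl_cluster(hits_to_graph(cf, all_ids=sorted(joined))))
        cos = [f for f in fams if f.is_cos]
        found = {(f.pine_members[0], f.spruce_members[0]) for f in cos}
        assert found == set(truth)

    def test_candidate_sets_shrink_monotonically(self):
        pine, spruce, within, cross, _ = simulate_cos_universe(seed=8)
        wf = filter_cos_hits(within)
        clusters = mcl_cluster(hits_to_graph(wf, all_ids=pine + spruce))
        ps = identify_singletons(pine, clusters)
        ss = identify_singletons(spruce, clusters)
        fams = identify_cos(ps, ss, mcl_cluster(hits_to_graph(
            [h for h in filter_cos_hits(cross)
             if h.query_id in ps | ss and h.subject_id in ps | ss],
            all_ids=sorted(ps | ss))))
        n_cos = sum(f.is_cos for f in fams)
        assert len(pine) + len(spruce) >= len(ps) + len(ss) >= 2 * n_cos


class TestCategories:
    def test_truth_table_total(self):
        """Category assignment is total over flag combinations with at
        least one evidence flag; all-false is the only invalid input."""
        seen = set()
        for bits in product([False, True], repeat=5):
            flags = CosFlags(*bits)
            if not any(bits):
                with pytest.raises(ValidationError):
                    categorize_one(flags)
                continue
            seen.add(categorize_one(flags))
        assert seen == {"A", "B", "C", "D", "E"}

    @pytest.mark.parametrize(
        "flags,expected",
        [
            (CosFlags(has_plaza_hit=True), "A"),
            (CosFlags(has_nr_hit=True), "B"),
            (CosFlags(has_maritime_hit=True), "C"),
            (CosFlags(in_tgi_only=True), "D"),
            (CosFlags(duplication_flag=True), "E"),
            (CosFlags(has_plaza_hit=True, duplication_flag=True), "E"),
            (CosFlags(has_plaza_hit=True, has_nr_hit=True), "A"),
        ],
    )
    def test_precedence(self, flags, expected):
        assert categorize_one(flags) == expected

    def test_categorize_assigns_only_cos(self):
        fams = identify_cos({"p1", "p2"}, {"s1", "s2"},
                            [{"p1", "s1"}, {"p2", "s2", "p1x"}])
        flags = {f.family_id: CosFlags(has_plaza_hit=True) for f in fams}
        categorize_cos(fams, flags)
        assert fams[0].category == ("A" if fams[0].is_cos else None)
        non_cos = [f for f in fams if not f.is_cos]
        assert all(f.category is None for f in non_cos)


class TestLgAlignment:
    def test_single_homologous_pair(self):
        orths = [(f"o{i}", "LG2_A", "LG2_B", 1.0) for i in range(12)]
        al = align_linkage_groups(orths)
        assert al.homologous_pairs == [("LG2_A", "LG2_B")]
        assert al.conflicts == []

    def test_below_anchor_threshold(self):
        orths = [("o1", "A1", "B1", 1.0), ("o2", "A1", "B1", 1.0)]
        al = align_linkage_groups(orths, min_anchors=3)
        assert al.homologous_pairs == []

    def test_discordant_orthologs_reported(self):
        orths, k = [], 0
        for lg in range(7):
            for _ in range(7):
                orths.append((f"c{k}", f"A{lg}", f"B{lg}", 1.0))
                k += 1
        orths = orths[:46]
        for j in range(4):
            orths.append((f"d{j}", f"A{j}", f"B{(j + 3) % 7}", 1.0))
        al = align_linkage_groups(orths)
        assert len(al.homologous_pairs) == 7
        assert sorted(al.conflicts) == ["d0", "d1", "d2", "d3"]

    def test_low_coverage_excluded(self):
        orths = [("lo", "A1", "B1", 0.5)] + [
            (f"o{i}", "A1", "B1", 0.9) for i in range(3)
        ]
        al = align_linkage_groups(orths, ortholog_min_cov=0.75)
        assert al.excluded_low_cov == ["lo"]
        assert al.counts[("A1", "B1")] == 3

    def test_missing_group_label_rejected(self):
        with pytest.raises(ValidationError):
            align_linkage_groups([("o1", None, "B1", 1.0)])
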