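import pytest

from holomem.records import FamilyAnnotation, ProteinRecord, SimilarityHit
from holomem.synthetic import load_truth
from holomem.two_level import (
    Level1Cluster,
    attach_profiles,
    build_cluster_graph,
    family_fractions,
    level1,
    level2,
)


def annotated_cluster(cid, n, profile, participating=True):
    c = Level1Cluster(cid, members=[f"{cid}_p{i}" for i in range(n)])
    c.pfam_profile = profile
    c.has_any_annotation = participating
    return c


class TestFamilyFractions:
    def test_fraction_counts_each_protein_once(self):
        members = [f"p{i}" for i in range(10)]
        anns = [FamilyAnnotation(f"p{i}", "PF00001", "Fam", "Family")
                for i in range(7)]
        anns += [FamilyAnnotation("p0", "PF00001", "Fam", "Family")]  # duplicate
        assert family_fractions(members, anns) == {"PF00001": 0.7}

    def test_domain_type_models_are_excluded(self):
        members = ["p0", "p1"]
        anns = [FamilyAnnotation("p0", "PF00002", "EGF", "Domain")]
        assert family_fractions(members, anns) == {}

    def test_full_annotation_gives_fraction_one(self):
        members = ["p0", "p1", "p2"]
        anns = [FamilyAnnotation(p, "PF00003", "Fam", "Family") for p in members]
        assert family_fractions(members, anns) == {"PF00003": 1.0}


class TestClusterGraph:
    def test_edge_weight_is_max_fraction_and_kept_at_threshold(self):
        a = annotated_cluster("A", 10, {"PF1": 0.7})
        b = annotated_cluster("B", 10, {"PF1": 0.5})
        graph, edges = build_cluster_graph([a, b])
        assert graph["A"]["B"]["weight"] == pytest.approx(0.7)
        assert edges[0].best_family == "PF1"

    def test_edge_below_threshold_dropped(self):
        a = annotated_cluster("A", 10, {"PF1": 0.4})
        b = annotated_cluster("B", 10, {"PF1": 0.45})
        graph, edges = build_cluster_graph([a, b])
        assert graph.number_of_edges() == 0 and edges == []

    def test_multiple_shared_families_collapse_to_max(self):
        a = annotated_cluster("A", 10, {"PF1": 0.55, "PF2": 0.9})
        b = annotated_cluster("B", 10, {"PF1": 0.55, "PF2": 0.9})
        graph, edges = build_cluster_graph([a, b])
        assert graph.number_of_edges() == 1
        assert graph["A"]["B"]["weight"] == pytest.approx(0.9)
        assert edges[0].best_family == "PF2"

    def test_non_participating_clusters_excluded(self):
        a = annotated_cluster("A", 5, {"PF1": 1.0})
        b = annotated_cluster("B", 5, {"PF1": 1.0}, participating=False)
        graph, _ = build_cluster_graph([a, b])
        assert set(graph.nodes) == {"A"}

    def test_threshold_monotonicity(self):
        clusters = [
            annotated_cluster("A", 10, {"PF1": 0.9, "PF2": 0.6}),
            annotated_cluster("B", 10, {"PF1": 0.55}),
            annotated_cluster("C", 10, {"PF2": 0.7}),
            annotated_cluster("D", 10, {"PF3": 0.5}),
        ]
        previous = None
        for threshold in (0.3, 0.5, 0.7, 0.9, 1.01):
            graph, _ = build_cluster_graph(clusters, threshold=threshold)
            units = level2(clusters, graph)
            n_merges = sum(len(u.member_cluster_ids) - 1 for u in units)
            if previous is not None:
                assert n_merges <= previous
            previous = n_merges


class TestLevel2:
    def test_linked_pair_merges(self):
        a = annotated_cluster("A", 3, {"PF1": 0.9})
        b = annotated_cluster("B", 3, {"PF1": 0.9})
        graph, _ = build_cluster_graph([a, b])
        units = level2([a, b], graph)
        assert len(units) == 1
        assert sorted(units[0].member_cluster_ids) == ["A", "B"]

    def test_isolated_participating_cluster_is_a_level2_singleton(self):
        a = annotated_cluster("A", 3, {"PF1": 0.9})
        graph, _ = build_cluster_graph([a])
        units = level2([a], graph)
        assert len(units) == 1 and units[0].member_cluster_ids == ["A"]

    def test_pass_through_keeps_distinct_prefix_and_conserves_proteins(self):
        a = annotated_cluster("A", 3, {"PF1": 0.9})
        b = annotated_cluster("B", 2, {}, participating=False)
        graph, _ = build_cluster_graph([a, b])
        units = level2([a, b], graph)
        ids = sorted(u.cluster_id for u in units)
        assert any(cid.startswith("PT_") for cid in ids)
        proteins = [p for u in units for p in u.members]
        assert sorted(proteins) == sorted(a.members + b.members)
        assert len(set(proteins)) == len(proteins)

    def test_order_invariance_of_level2(self):
        clusters = [annotated_cluster("A", 4, {"PF1": 0.8}),
                    annotated_cluster("B", 4, {"PF1": 0.8}),
                    annotated_cluster("C", 4, {"PF2": 0.9})]
        graph, _ = build_cluster_graph(clusters)
        forward = level2(clusters, graph)
        backward = level2(list(reversed(clusters)), graph)
        assert [sorted(u.member_cluster_ids) for u in forward] == \
            [sorted(u.member_cluster_ids) for u in backward]


class TestLevel1:
    def test_protein_without_hits_becomes_singlet(self):
        rec = ProteinRecord("p1", "g1", "spA", 100, tm_count=2)
        clusters = level1([], [rec])
        assert len(clusters) == 1 and clusters[0].is_singlet

    def test_weak_spurious_bridge_does_not_merge_families(self):
        # two 4-protein families with intra-hits at 1e-100 and a single
        # cross-hit at e=0.009 (weight ~2.05)
        records, hits = [], []
        for fam, prefix in enumerate("ab"):
            for i in range(4):
                records.append(ProteinRecord(f"{prefix}{i}", f"g_{prefix}{i}",
                                             "spA", 100, tm_count=1))
            ids = [f"{prefix}{i}" for i in range(4)]
            hits += [SimilarityHit(q, s, 1e-100)
                     for q in ids for s in ids if q != s]
        hits.append(SimilarityHit("a0", "b0", 0.009))
        clusters = level1(hits, records)
        got = {frozenset(c.members) for c in clusters}
        assert got == {frozenset(f"a{i}" for i in range(4)),
                       frozenset(f"b{i}" for i in range(4))}

    def test_zero_noise_bundle_recovers_planted_families(self, small_bundle):
        paths, truth, result = small_bundle
        got = {frozenset(c.members) for c in result.level1}
        planted = {}
        for pid, fam in truth.protein_to_family.items():
            planted.setdefault(fam, set()).add(pid)
        assert got == {frozenset(v) for v in planted.values()}

    def test_every_membrane_protein_traceable_to_one_level2_unit(
            self, small_bundle):
        _, _, result = small_bundle
        unit_members = [p for u in result.level2 for p in u.members]
        assert sorted(unit_members) == \
            sorted(p.protein_id for p in result.membrane_proteins)
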