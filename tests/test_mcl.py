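import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, strategies as st

from holomem.errors import DataError
from holomem.mcl import (
    MclParams,
    build_similarity_graph,
    cluster_stats,
    evalue_weight,
    mcl,
    read_abc,
    write_abc,
)
from holomem.records import SimilarityHit


def naive_mcl_partition(graph, inflation, iterations=200):
    """Straightforward MCL reference: no pruning, components of the
    converged nonzero structure. Independent of the package's
    attractor-based implementation."""
    nodes = sorted(graph.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    a = np.zeros((n, n))
    for u, v, d in graph.edges(data=True):
        a[idx[u], idx[v]] = a[idx[v], idx[u]] = d["weight"]
    loops = a.max(axis=0)
    loops[loops == 0] = 1.0
    np.fill_diagonal(a, loops)
    m = a / a.sum(axis=0)
    for _ in range(iterations):
        m = np.linalg.matrix_power(m, 2) ** inflation
        m /= m.sum(axis=0)
    structure = nx.from_numpy_array((m > 1e-9) | (m.T > 1e-9))
    return {frozenset(nodes[i] for i in comp)
            for comp in nx.connected_components(structure)}


def clique_graph(cliques, weight=20.0, bridges=()):
    g = nx.Graph()
    for clique in cliques:
        for i, u in enumerate(clique):
            for v in clique[i + 1:]:
                g.add_edge(u, v, weight=weight)
    for u, v, w in bridges:
        g.add_edge(u, v, weight=w)
    return g


class TestEvalueWeight:
    @pytest.mark.parametrize("evalue,expected", [
        (0.01, 2.0),        # -log10(0.01) by hand
        (1e-300, 200.0),    # capped
        (0.0, 200.0),       # cap is the only finite choice
        (1e-10, 10.0),
    ])
    def test_transform(self, evalue, expected):
        assert evalue_weight(evalue) == pytest.approx(expected)

    def test_weak_evalue_clamps_to_positive_floor(self):
        assert 0 < evalue_weight(1.0) < 1
        assert 0 < evalue_weight(5.0) < 1

    def test_negative_evalue_is_a_data_error(self):
        with pytest.raises(DataError):
            evalue_weight(-1e-5)


class TestBuildGraph:
    def test_mirrored_directions_resolve_to_best_evalue(self):
        g = build_similarity_graph([SimilarityHit("A", "B", 1e-10),
                                    SimilarityHit("B", "A", 1e-8)])
        assert g["A"]["B"]["weight"] == pytest.approx(10.0)

    def test_isolated_protein_appears_as_node(self):
        g = build_similarity_graph([], nodes=["solo"])
        assert g.number_of_nodes() == 1 and g.number_of_edges() == 0

    def test_triangle_weights(self):
        hits = [SimilarityHit(a, b, 1e-20)
                for a in "ABC" for b in "ABC" if a != b]
        g = build_similarity_graph(hits)
        assert all(math.isclose(d["weight"], 20.0)
                   for _, _, d in g.edges(data=True))


class TestMcl:
    def test_disconnected_cliques_stay_separate(self):
        g = clique_graph([list("abc"), list("xyz")])
        partition = mcl(g, MclParams(inflation=1.6))
        assert set(map(frozenset, partition.values())) == \
            {frozenset("abc"), frozenset("xyz")}

    def test_isolated_nodes_become_singletons(self):
        g = nx.Graph()
        g.add_nodes_from("abcde")
        partition = mcl(g)
        assert sorted(len(c) for c in partition.values()) == [1] * 5

    def test_bridged_cliques_split_and_match_reference(self):
        g = clique_graph([list("abcd"), list("wxyz")],
                         weight=20.0, bridges=[("d", "w", 2.0)])
        partition = mcl(g, MclParams(inflation=1.6))
        got = set(map(frozenset, partition.values()))
        assert got == {frozenset("abcd"), frozenset("wxyz")}
        assert got == naive_mcl_partition(g, inflation=1.6)

    @pytest.mark.parametrize("inflation", [1.4, 1.6, 1.8, 2.0])
    def test_planted_two_block_recovery(self, inflation):
        rng = np.random.default_rng(5)
        g = nx.Graph()
        blocks = [[f"a{i}" for i in range(6)], [f"b{i}" for i in range(6)]]
        for block in blocks:
            for i, u in enumerate(block):
                for v in block[i + 1:]:
                    g.add_edge(u, v, weight=float(rng.uniform(15, 25)))
        g.add_edge("a0", "b0", weight=1.5)  # intra/inter ratio >= 10
        partition = mcl(g, MclParams(inflation=inflation))
        assert set(map(frozenset, partition.values())) == \
            {frozenset(blocks[0]), frozenset(blocks[1])}

    def test_partition_exactness_and_component_confinement(self):
        rng = np.random.default_rng(7)
        g = nx.gnm_random_graph(30, 60, seed=3)
        g = nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes})
        for u, v in g.edges:
            g[u][v]["weight"] = float(rng.uniform(1, 30))
        partition = mcl(g)
        members = [m for c in partition.values() for m in c]
        assert len(members) == g.number_of_nodes()  # disjoint cover
        assert len(set(members)) == len(members)
        comp_of = {}
        for i, comp in enumerate(nx.connected_components(g)):
            for n in comp:
                comp_of[n] = i
        for cluster in partition.values():
            assert len({comp_of[n] for n in cluster}) == 1

    def test_label_permutation_invariance(self):
        g = clique_graph([list("abcd"), list("wxyz")],
                         bridges=[("d", "w", 2.0)])
        mapping = {n: f"Q_{n}" for n in g.nodes}
        relabeled = nx.relabel_nodes(g, mapping)
        base = set(map(frozenset, mcl(g).values()))
        relab = set(map(frozenset, mcl(relabeled).values()))
        assert {frozenset(mapping[n] for n in c) for c in base} == relab

    def test_columns_stay_stochastic_through_iterations(self):
        g = clique_graph([list("abcd"), list("wxyz")],
                         bridges=[("d", "w", 2.0)])
        seen = []

        def check(m):
            colsums = m.sum(axis=0)
            live = colsums > 0  # fully pruned columns are allowed to be zero
            assert np.allclose(colsums[live], 1.0, atol=1e-9)
            seen.append(True)

        mcl(g, on_iteration=check)
        assert seen


class TestClusterStats:
    def test_counts_and_singletons(self):
        stats = cluster_stats({0: frozenset("ab"), 1: frozenset("c")})
        assert (stats.n_clusters, stats.n_singletons) == (2, 1)
        assert stats.n_nodes == 3

    def test_empty_partition(self):
        stats = cluster_stats({})
        assert (stats.n_clusters, stats.n_singletons, stats.n_nodes) == (0, 0, 0)


def test_abc_roundtrip(tmp_path):
    g = clique_graph([list("abc")], weight=12.5)
    path = tmp_path / "graph.abc"
    write_abc(g, path)
    back = read_abc(path)
    assert set(back.edges) == set(g.edges)
    assert back["a"]["b"]["weight"] == pytest.approx(12.5)


@given(st.integers(0, 2**31 - 1))
def test_two_clique_recovery_over_random_weights(seed):
    rng = np.random.default_rng(seed)
    g = clique_graph([list("abc"), list("xyz")],
                     weight=float(rng.uniform(10, 200)))
    partition = mcl(g)
    assert set(map(frozenset, partition.values())) == \
        {frozenset("abc"), frozenset("xyz")}
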