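"""Weighted homology graphs and an in-package Markov Cluster algorithm.

The clustering follows the classic MCL iteration: add self-loops, column
normalise to a stochastic matrix, then alternate expansion (matrix
squaring) and inflation (entrywise power followed by column
renormalisation) with pruning of vanishing entries, until the per-column
chaos drops below tolerance. Clusters are read off the converged matrix
through its attractor structure.

Because expansion cannot mix disconnected components, the input graph is
split into connected components first and the dense iteration runs per
component; this keeps the dense representation honest at desk scale
while remaining exact.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable

import networkx as nx
import numpy as np

from .errors import DataError
from .records import SimilarityHit

#: Weight assigned to a hit with e-value >= 1 (-log10 would be <= 0, and
#: MCL edge weights must stay positive). Hits that weak are normally
#: removed by the 0.01 e-value threshold before the graph is built.
MIN_EDGE_WEIGHT = 1e-3

DEFAULT_WEIGHT_CAP = 200.0


def evalue_weight(evalue: float, cap: float = DEFAULT_WEIGHT_CAP,
                  floor: float = MIN_EDGE_WEIGHT) -> float:
    """Transform a BLAST e-value into an edge weight: min(-log10 e, cap).

    An e-value of exactly 0 maps to the cap (the only finite choice);
    e-values >= 1 are clamped to a small positive floor.
    """
    if evalue < 0:
        raise DataError(f"negative e-value {evalue}")
    if evalue == 0:
        return cap
    w = -math.log10(evalue)
    if w <= 0:
        return floor
    return min(w, cap)


def build_similarity_graph(
    hits: Iterable[SimilarityHit],
    nodes: Iterable[str] | None = None,
    cap: float = DEFAULT_WEIGHT_CAP,
) -> nx.Graph:
    """Undirected homology network with capped -log10 e-value weights.

    Duplicate hits for one unordered pair (the mirrored direction, or
    multiple HSPs) resolve to the best e-value, i.e. the maximum weight.
    ``nodes`` (e.g. the full membrane proteome) are all added so that
    proteins without qualifying hits appear as isolated nodes.
    """
    g = nx.Graph()
    if nodes is not None:
        g.add_nodes_from(nodes)
    for h in hits:
        if h.query_id == h.subject_id:
            continue
        w = evalue_weight(h.evalue, cap=cap)
        if g.has_edge(h.query_id, h.subject_id):
            if w > g[h.query_id][h.subject_id]["weight"]:
                g[h.query_id][h.subject_id]["weight"] = w
        else:
            g.add_edge(h.query_id, h.subject_id, weight=w)
    return g


@dataclass
class MclParams:
    inflation: float = 1.6
    prune_threshold: float = 1e-6
    max_iterations: int = 200
    convergence_tol: float = 1e-8
    loop_policy: str = "max-incident-weight"  # or "unit"

    def __post_init__(self):
        if self.inflation <= 1:
            raise DataError(f"inflation must be > 1, got {self.inflation}")
        if self.prune_threshold < 0:
            raise DataError("prune_threshold must be >= 0")
        if self.convergence_tol <= 0:
            raise DataError("convergence_tol must be > 0")
        if self.loop_policy not in ("max-incident-weight", "unit"):
            raise DataError(f"unknown loop_policy {self.loop_policy!r}")


Partition = dict[int, frozenset]


def mcl(graph: nx.Graph, params: MclParams | None = None,
        on_iteration: Callable[[np.ndarray], None] | None = None) -> Partition:
    """Cluster a weighted undirected graph with the Markov Cluster algorithm.

    Returns a partition ``cluster_id -> member set``; ids are assigned
    deterministically (0..k-1 ordered by each cluster's smallest member).
    Isolated nodes come out as singletons. A component that has not
    converged after ``max_iterations`` is interpreted as-is.
    """
    params = params or MclParams()
    clusters: list[frozenset] = []
    for comp in nx.connected_components(graph):
        if len(comp) == 1:
            clusters.append(frozenset(comp))
            continue
        sub = graph.subgraph(comp)
        clusters.extend(_mcl_component(sub, params, on_iteration))
    ordered = sorted(clusters, key=lambda c: min(c))
    return {i: c for i, c in enumerate(ordered)}


def _mcl_component(sub: nx.Graph, params: MclParams,
                   on_iteration=None) -> list[frozenset]:
    nodes = sorted(sub.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    a = np.zeros((n, n))
    for u, v, data in sub.edges(data=True):
        w = float(data["weight"])
        if w <= 0:
            raise DataError(f"non-positive edge weight on {u}-{v}")
        a[index[u], index[v]] = w
        a[index[v], index[u]] = w
    # self-loops
    if params.loop_policy == "max-incident-weight":
        loops = a.max(axis=0)
        loops[loops == 0] = 1.0
    else:
        loops = np.ones(n)
    np.fill_diagonal(a, loops)

    m = a / a.sum(axis=0, keepdims=True)
    for _ in range(params.max_iterations):
        m = m @ m  # expansion
        np.power(m, params.inflation, out=m)  # inflation
        m /= m.sum(axis=0, keepdims=True)
        if params.prune_threshold > 0:
            m[m < params.prune_threshold] = 0.0
            colsum = m.sum(axis=0, keepdims=True)
            colsum[colsum == 0] = 1.0  # fully pruned column: leave zero
            m /= colsum
        if on_iteration is not None:
            on_iteration(m.copy())
        chaos = (m.max(axis=0) - (m * m).sum(axis=0)).max()
        if chaos < params.convergence_tol:
            break

    return _interpret(m, nodes)


def _interpret(m: np.ndarray, nodes: list) -> list[frozenset]:
    """Read clusters off a converged MCL matrix via its attractors.

    Attractors (nonzero diagonal) that flow into each other share a
    cluster; every other node joins the cluster(s) of the attractors
    whose rows reach it. A node reached by several attractor systems is
    assigned to the cluster with the smallest id; a node reached by none
    (numerically starved) becomes a singleton.
    """
    n = len(nodes)
    eps = 1e-12
    attractors = [i for i in range(n) if m[i, i] > eps]
    if not attractors:  # degenerate; fall back to nonzero structure
        structure = nx.from_numpy_array((m > eps) | (m.T > eps))
        return [frozenset(nodes[i] for i in comp)
                for comp in nx.connected_components(structure)]
    # group attractors that reach one another
    ag = nx.Graph()
    ag.add_nodes_from(attractors)
    for i in attractors:
        for j in attractors:
            if i < j and (m[i, j] > eps or m[j, i] > eps):
                ag.add_edge(i, j)
    systems = [sorted(c) for c in nx.connected_components(ag)]
    systems.sort(key=lambda s: s[0])
    member_sets: list[set] = [set(s) for s in systems]
    assigned = {i for s in member_sets for i in s}
    for j in range(n):
        if j in assigned:
            continue
        for k, system in enumerate(systems):
            if any(m[i, j] > eps for i in system):
                member_sets[k].add(j)  # smallest cluster id wins
                break
        else:
            member_sets.append({j})
    return [frozenset(nodes[i] for i in s) for s in member_sets if s]


@dataclass
class ClusterStats:
    n_clusters: int
    n_singletons: int
    size_histogram: Counter

    @property
    def n_nodes(self) -> int:
        return sum(size * count for size, count in self.size_histogram.items())


def cluster_stats(partition: Partition) -> ClusterStats:
    sizes = Counter(len(c) for c in partition.values())
    return ClusterStats(
        n_clusters=len(partition),
        n_singletons=sizes.get(1, 0),
        size_histogram=sizes,
    )


# ---------------------------------------------------------------------------
# ABC interchange format (node1 TAB node2 TAB weight)


def write_abc(graph: nx.Graph, path: str | Path) -> None:
    with open(path, "w") as fh:
        for u, v, data in sorted(graph.edges(data=True)):
            fh.write(f"{u}\t{v}\t{data['weight']:.6g}\n")


def read_abc(path: str | Path) -> nx.Graph:
    g = nx.Graph()
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            u, v, w = line.rstrip("\n").split("\t")
            g.add_edge(u, v, weight=float(w))
    return g
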