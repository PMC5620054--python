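"""Two-level clustering: BLAST similarity, then Pfam-family composition.

Level 1 groups membrane proteins by sequence similarity (MCL at
inflation 1.6 on the capped -log10 e-value network). Level 2 groups the
level-1 clusters that carry any annotation, connecting two clusters when
they share a Family-type Pfam model; the edge weight is the larger of
the two member fractions for that model, and edges below 0.5 are
dropped before MCL at inflation 1.8. Repeat/Domain-type models never
drive level-2 edges, which keeps promiscuous domains from gluing
unrelated families together.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx

from .mcl import MclParams, build_similarity_graph, mcl
from .records import Cluster, FamilyAnnotation, ProteinRecord, SimilarityHit

LEVEL2_WEIGHT_THRESHOLD = 0.5
PASS_THROUGH_PREFIX = "PT_"


@dataclass
class Level1Cluster:
    cluster_id: str
    members: list[str]  # sorted protein ids
    species_counts: Counter = field(default_factory=Counter)
    pfam_profile: dict[str, float] = field(default_factory=dict)  # Family-type only
    has_any_annotation: bool = False  # any Pfam model type, or proxy function
    is_singlet: bool = False

    @property
    def size(self) -> int:
        return len(self.members)


def level1(
    hits: Iterable[SimilarityHit],
    membrane: list[ProteinRecord],
    params: MclParams | None = None,
) -> list[Level1Cluster]:
    """Cluster the membrane proteome on the similarity network.

    Hits touching proteins outside the membrane set are ignored; every
    membrane protein lands in exactly one cluster (proteins without
    qualifying hits become singlets).
    """
    params = params or MclParams(inflation=1.6)
    species_of = {r.protein_id: r.species_id for r in membrane}
    kept = [h for h in hits
            if h.query_id in species_of and h.subject_id in species_of]
    graph = build_similarity_graph(kept, nodes=species_of.keys())
    partition = mcl(graph, params)
    clusters = []
    for i, members in sorted(partition.items()):
        ms = sorted(members)
        clusters.append(Level1Cluster(
            cluster_id=f"L1_{i:05d}",
            members=ms,
            species_counts=Counter(species_of[p] for p in ms),
            is_singlet=len(ms) == 1,
        ))
    return clusters


def family_fractions(members: list[str],
                     annotations: Iterable[FamilyAnnotation]) -> dict[str, float]:
    """Fraction of cluster members carrying each Family-type Pfam model.

    A protein annotated several times with one accession counts once.
    """
    member_set = set(members)
    carriers: dict[str, set] = defaultdict(set)
    for a in annotations:
        if a.is_family_type and a.protein_id in member_set:
            carriers[a.pfam_accession].add(a.protein_id)
    n = len(members)
    return {acc: len(prots) / n for acc, prots in sorted(carriers.items())}


def attach_profiles(
    clusters: list[Level1Cluster],
    annotations: list[FamilyAnnotation],
    proteins_with_function: set[str] | None = None,
) -> None:
    """Fill each cluster's Family-type profile and its participation flag.

    A cluster participates in level 2 when any member has a Pfam
    annotation of any model type and/or an associated function (the
    human-proxy annotation table).
    """
    annotated = {a.protein_id for a in annotations}
    with_function = proteins_with_function or set()
    by_cluster: dict[str, list[FamilyAnnotation]] = defaultdict(list)
    member_cluster = {p: c.cluster_id for c in clusters for p in c.members}
    for a in annotations:
        cid = member_cluster.get(a.protein_id)
        if cid is not None:
            by_cluster[cid].append(a)
    for c in clusters:
        c.pfam_profile = family_fractions(c.members, by_cluster.get(c.cluster_id, []))
        c.has_any_annotation = any(
            p in annotated or p in with_function for p in c.members)


@dataclass(frozen=True)
class FamilyEdge:
    cluster_a: str
    cluster_b: str
    best_family: str
    weight: float


def build_cluster_graph(
    clusters: list[Level1Cluster],
    threshold: float = LEVEL2_WEIGHT_THRESHOLD,
) -> tuple[nx.Graph, list[FamilyEdge]]:
    """Connect participating level-1 clusters that share a Family model.

    Per shared accession the candidate weight is the larger member
    fraction of the two clusters; multiple shared accessions collapse to
    one edge carrying the maximum weight. Edges below ``threshold`` are
    dropped.
    """
    participating = [c for c in clusters if c.has_any_annotation]
    g = nx.Graph()
    g.add_nodes_from(c.cluster_id for c in participating)
    by_family: dict[str, list[Level1Cluster]] = defaultdict(list)
    for c in participating:
        for acc in c.pfam_profile:
            by_family[acc].append(c)
    best: dict[tuple[str, str], tuple[float, str]] = {}
    for acc, cs in sorted(by_family.items()):
        for i in range(len(cs)):
            for j in range(i + 1, len(cs)):
                a, b = cs[i], cs[j]
                w = max(a.pfam_profile[acc], b.pfam_profile[acc])
                key = tuple(sorted((a.cluster_id, b.cluster_id)))
                if key not in best or w > best[key][0]:
                    best[key] = (w, acc)
    edges = []
    for (ca, cb), (w, acc) in sorted(best.items()):
        if w >= threshold:
            g.add_edge(ca, cb, weight=w, best_family=acc)
            edges.append(FamilyEdge(ca, cb, acc, w))
    return g, edges


def level2(
    clusters: list[Level1Cluster],
    cluster_graph: nx.Graph,
    params: MclParams | None = None,
) -> list[Cluster]:
    """Group level-1 clusters on the shared-family network.

    Non-participating level-1 clusters pass through unchanged as their
    own level-2 units (ids prefixed ``PT_``) so that every membrane
    protein remains traceable to exactly one unit.
    """
    params = params or MclParams(inflation=1.8)
    by_id = {c.cluster_id: c for c in clusters}
    partition = mcl(cluster_graph, params)
    units = []
    for i, member_ids in sorted(partition.items()):
        ids = sorted(member_ids)
        proteins = sorted(p for cid in ids for p in by_id[cid].members)
        units.append(Cluster(cluster_id=f"L2_{i:05d}", level=2,
                             members=proteins, member_cluster_ids=ids))
    clustered = {cid for u in units for cid in u.member_cluster_ids}
    for c in clusters:
        if c.cluster_id not in clustered:
            units.append(Cluster(cluster_id=f"{PASS_THROUGH_PREFIX}{c.cluster_id}",
                                 level=2, members=list(c.members),
                                 member_cluster_ids=[c.cluster_id]))
    units.sort(key=lambda u: u.cluster_id)
    return units
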