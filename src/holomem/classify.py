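"""Rule-based functional classification of proteins and clusters.

Per-protein precedence: an EC number makes an enzyme (subclass = first
two EC fields), a transporter-classification (TCDB) identifier makes a
transporter, then the curated receptor/other call, then a DUF-only Pfam
annotation (other + DUF flag), then no_description. Cluster labels are
strict-majority consensus over classified human-proxy members, falling
back to a Pfam-accession-to-class mapping when the cluster contains no
classified proxy protein.
"""

from __future__ import annotations

import logging
from collections import Counter

from .records import (
    MAIN_CLASSES,
    Cluster,
    FamilyAnnotation,
    FunctionalLabel,
    HumanAnnotation,
)
from .two_level import Level1Cluster

logger = logging.getLogger(__name__)


def ec_subclass(ec_number: str) -> str:
    """First two EC fields, e.g. ``2.4.1.-`` -> ``EC 2.4``."""
    parts = ec_number.split(".")
    return "EC " + ".".join(parts[:2])


def classify_protein(
    ann: HumanAnnotation | None,
    pfam: list[FamilyAnnotation] | None = None,
) -> FunctionalLabel:
    pfam = pfam or []
    if ann is not None:
        if ann.ec_number:
            if ann.tcdb_id:
                logger.info("%s carries both EC and TCDB; EC takes precedence",
                            ann.protein_id)
            return FunctionalLabel("enzyme", subclass=ec_subclass(ann.ec_number))
        if ann.tcdb_id:
            return FunctionalLabel("transporter", subclass=ann.tcdb_id)
        if ann.curated_class:
            return FunctionalLabel(ann.curated_class)
    duf = [a for a in pfam if a.is_duf]
    if duf and len(duf) == len(pfam):
        return FunctionalLabel("other", duf_flag=True)
    return FunctionalLabel("no_description")


def _majority(classes: list[str]) -> str | None:
    """Strict majority (> 50%) class, or None on a tie / empty input."""
    if not classes:
        return None
    counts = Counter(classes)
    cls, n = counts.most_common(1)[0]
    return cls if n * 2 > len(classes) else None


def consensus_level1(
    cluster: Level1Cluster,
    protein_labels: dict[str, FunctionalLabel],
    proxy_proteins: set[str],
    pfam_class_map: dict[str, str] | None = None,
) -> FunctionalLabel:
    """Consensus class for a level-1 cluster.

    Classified human-proxy members vote; a strict majority wins and an
    unresolved tie is ambiguous (consensus failed). With no classified
    proxy member the cluster falls back to the Pfam-derived class of its
    best-represented mapped Family model, else no_description.
    """
    votes = [protein_labels[p].cls for p in cluster.members
             if p in proxy_proteins and p in protein_labels
             and protein_labels[p].cls in MAIN_CLASSES]
    if votes:
        winner = _majority(votes)
        if winner is None:
            return FunctionalLabel("ambiguous")
        duf = any(protein_labels[p].duf_flag for p in cluster.members
                  if p in protein_labels)
        return FunctionalLabel(winner, duf_flag=duf)
    if pfam_class_map:
        mapped = [(frac, acc) for acc, frac in cluster.pfam_profile.items()
                  if acc in pfam_class_map]
        if mapped:
            # highest member fraction decides; smallest accession breaks ties
            top = max(frac for frac, _ in mapped)
            acc = min(acc for frac, acc in mapped if frac == top)
            return FunctionalLabel(pfam_class_map[acc])
    return FunctionalLabel("no_description")


def classify_level2(
    unit: Cluster,
    level1_labels: dict[str, FunctionalLabel],
) -> FunctionalLabel:
    """Label a level-2 unit from its member level-1 labels.

    Unanimity among classified members wins outright; a strict majority
    wins with the conflict logged; otherwise the unit is ambiguous and,
    when its members carry heterogeneous (or no consistent) Pfam-based
    classes, flagged as varied-Pfam.
    """
    labels = [level1_labels[cid] for cid in unit.member_cluster_ids
              if cid in level1_labels]
    classified = [lab.cls for lab in labels if lab.cls in MAIN_CLASSES]
    duf = any(lab.duf_flag for lab in labels)
    if not classified:
        if any(lab.cls == "ambiguous" for lab in labels):
            return FunctionalLabel("ambiguous", varied_pfam_flag=True, duf_flag=duf)
        return FunctionalLabel("no_description", duf_flag=duf)
    distinct = set(classified)
    if len(distinct) == 1:
        lab = FunctionalLabel(classified[0], duf_flag=duf)
    else:
        winner = _majority(classified)
        if winner is None:
            return FunctionalLabel("ambiguous", varied_pfam_flag=True, duf_flag=duf)
        logger.info("%s: minority classes %s overruled by %s", unit.cluster_id,
                    sorted(distinct - {winner}), winner)
        lab = FunctionalLabel(winner, duf_flag=duf)
    # carry a subclass when the winning members agree on one
    subs = {level1_labels[cid].subclass for cid in unit.member_cluster_ids
            if cid in level1_labels and level1_labels[cid].cls == lab.cls
            and level1_labels[cid].subclass}
    if len(subs) == 1:
        lab.subclass = subs.pop()
    return lab


def annotate_singlets(
    clusters: list[Level1Cluster],
    labels: dict[str, FunctionalLabel],
) -> dict[str, FunctionalLabel]:
    """Flag species-specific singlet clusters that still carry annotation.

    A singlet with any annotation keeps its label and gains the
    annotated-singlet flag; a singlet with nothing is no_description.
    Non-singlets are returned unchanged.
    """
    out = {}
    for c in clusters:
        lab = labels.get(c.cluster_id, FunctionalLabel("no_description"))
        if c.is_singlet:
            if c.has_any_annotation and lab.cls != "no_description":
                lab.annotated_singlet_flag = True
            elif not c.has_any_annotation:
                lab = FunctionalLabel("no_description")
        out[c.cluster_id] = lab
    return out
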