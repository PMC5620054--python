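"""End-to-end pipeline: prepare -> membrane filter -> level-1 -> profiles
-> level-2 -> classify -> compare, with a JSON run manifest.

Every stage writes its table under the run directory; ``report`` renders
those tables without recomputation. Reruns on identical inputs and
configuration are bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import classify as _classify
from . import comparative, io_formats, membrane, two_level
from .errors import DataError, HolomemError
from .mcl import MclParams
from .records import Cluster, FunctionalLabel, ProteinRecord
from .stats import integer_percent

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Stage parameters; the defaults are the published values
    (e-value 0.01, weight cap 200, inflation 1.6 / 1.8, level-2 weight
    threshold 0.5)."""

    fasta_dir: str = "fasta"
    hits: str = "hits.m8"
    pfam: str = "pfam.tsv"
    topology: str = "topology.tsv"
    species: str = "species.tsv"
    human_annotations: str = "human_annotations.tsv"
    pfam_class_map: str = "pfam_class_map.tsv"
    max_evalue: float = 0.01
    weight_cap: float = 200.0
    inflation_level1: float = 1.6
    inflation_level2: float = 1.8
    level2_threshold: float = 0.5
    lhca_include_zero_outgroup: bool = True
    prune_threshold: float = 1e-6
    max_iterations: int = 200
    convergence_tol: float = 1e-8
    id_allowlist: str | None = None

    @classmethod
    def for_bundle(cls, bundle_root: str | Path, **overrides) -> "PipelineConfig":
        root = Path(bundle_root)
        return cls(
            fasta_dir=str(root / "fasta"),
            hits=str(root / "hits.m8"),
            pfam=str(root / "pfam.tsv"),
            topology=str(root / "topology.tsv"),
            species=str(root / "species.tsv"),
            human_annotations=str(root / "human_annotations.tsv"),
            pfam_class_map=str(root / "pfam_class_map.tsv"),
            **overrides,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


@dataclass
class RunResult:
    outdir: Path
    proteins: list[ProteinRecord]
    membrane_proteins: list[ProteinRecord]
    membrane_summaries: list[membrane.MembraneSummary]
    level1: list[two_level.Level1Cluster]
    level2: list[Cluster]
    level1_labels: dict[str, FunctionalLabel]
    level2_labels: dict[str, FunctionalLabel]
    count_matrix: pd.DataFrame
    manifest: dict = field(default_factory=dict)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run(config: PipelineConfig, outdir: str | Path) -> RunResult:
    """Execute all stages; any stage failure aborts naming the stage."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "stages": {}}

    inputs = {
        "hits": Path(config.hits), "pfam": Path(config.pfam),
        "topology": Path(config.topology), "species": Path(config.species),
        "human_annotations": Path(config.human_annotations),
    }
    for name, path in inputs.items():
        if not path.exists():
            raise DataError(f"stage '{name}': missing input {path}")
    manifest["input_checksums"] = {
        name: _sha256(path) for name, path in sorted(inputs.items())}

    try:
        species = io_formats.read_species(config.species)

        # --- prepare: FASTA -> longest isoform -> topology join -> excision
        stage = "prepare"
        allowlist = None
        if config.id_allowlist:
            allowlist = set(Path(config.id_allowlist).read_text().split())
        topology = io_formats.read_topology(config.topology)
        proteins: list[ProteinRecord] = []
        per_species_counts = {}
        for sp in species:
            fasta = Path(config.fasta_dir) / f"{sp.species_id}.fasta"
            if not fasta.exists():
                raise DataError(f"stage 'prepare': missing FASTA {fasta}")
            records = io_formats.read_fasta(fasta, sp.species_id)
            records = io_formats.filter_by_allowlist(records, allowlist)
            kept = io_formats.select_longest_isoform(records)
            for rec in kept:
                pr = rec.to_record()
                topo = topology.get(pr.protein_id)
                if topo is not None:
                    pr.tm_count, pr.has_signal_peptide, pr.signal_cut_site = topo
                    membrane.excise_signal(pr)  # validates cut-site bookkeeping
                proteins.append(pr)
            per_species_counts[sp.species_id] = len(kept)
        manifest["stages"][stage] = {"genes_per_species": per_species_counts,
                                     "proteins": len(proteins)}

        # --- membrane filter
        stage = "membrane"
        membrane_proteins: list[ProteinRecord] = []
        summaries = []
        for sp in species:
            sp_records = [p for p in proteins if p.species_id == sp.species_id]
            mem, summary = membrane.membrane_proteome(sp_records, sp.species_id)
            membrane_proteins.extend(mem)
            summaries.append(summary)
        io_formats._write_tsv(
            outdir / "membrane_summary.tsv",
            ["species", "total", "membrane", "percent", "skipped"],
            ((s.species_id, s.total, s.membrane, s.percent, len(s.skipped))
             for s in summaries))
        manifest["stages"][stage] = {
            "membrane_proteins": len(membrane_proteins),
            "skipped": sum(len(s.skipped) for s in summaries)}

        # --- level 1
        stage = "cluster1"
        hits = io_formats.read_hits(config.hits, max_evalue=config.max_evalue)
        params1 = MclParams(inflation=config.inflation_level1,
                            prune_threshold=config.prune_threshold,
                            max_iterations=config.max_iterations,
                            convergence_tol=config.convergence_tol)
        l1 = two_level.level1(hits, membrane_proteins, params1)
        manifest["stages"][stage] = {
            "hits_used": len(hits), "clusters": len(l1),
            "singlets": sum(c.is_singlet for c in l1)}

        # --- profiles
        stage = "profile"
        annotations = io_formats.read_pfam(config.pfam)
        human_anns = io_formats.read_human_annotations(config.human_annotations)
        two_level.attach_profiles(l1, annotations, set(human_anns))
        manifest["stages"][stage] = {
            "annotations": len(annotations),
            "participating_clusters": sum(c.has_any_annotation for c in l1)}

        # --- level 2
        stage = "cluster2"
        graph, edges = two_level.build_cluster_graph(
            l1, threshold=config.level2_threshold)
        params2 = MclParams(inflation=config.inflation_level2,
                            prune_threshold=config.prune_threshold,
                            max_iterations=config.max_iterations,
                            convergence_tol=config.convergence_tol)
        l2 = two_level.level2(l1, graph, params2)
        io_formats._write_tsv(outdir / "level2_edges.tsv",
                              ["cluster1", "cluster2", "best_family", "weight"],
                              ((e.cluster_a, e.cluster_b, e.best_family,
                                f"{e.weight:.4f}") for e in edges))
        manifest["stages"][stage] = {"edges": len(edges), "units": len(l2)}

        # --- classification
        stage = "classify"
        pfam_by_protein: dict[str, list] = {}
        for a in annotations:
            pfam_by_protein.setdefault(a.protein_id, []).append(a)
        proxy_species = {s.species_id for s in species if s.is_human_proxy}
        proxy_proteins = {p.protein_id for p in proteins
                          if p.species_id in proxy_species}
        protein_labels = {
            pid: _classify.classify_protein(human_anns.get(pid),
                                            pfam_by_protein.get(pid))
            for pid in set(human_anns) | set(pfam_by_protein)}
        class_map = (io_formats.read_pfam_class_map(config.pfam_class_map)
                     if Path(config.pfam_class_map).exists() else {})
        l1_labels = {c.cluster_id: _classify.consensus_level1(
            c, protein_labels, proxy_proteins, class_map) for c in l1}
        l1_labels = _classify.annotate_singlets(l1, l1_labels)
        l2_labels = {u.cluster_id: _classify.classify_level2(u, l1_labels)
                     for u in l2}
        for u in l2:
            u.label = l2_labels[u.cluster_id]
        io_formats.write_clusters(l2, outdir / "level2_clusters.tsv")
        io_formats.write_clusters(
            [Cluster(c.cluster_id, 1, c.members, [],
                     l1_labels[c.cluster_id]) for c in l1],
            outdir / "level1_clusters.tsv")
        class_counts: dict[str, int] = {}
        for u in l2:
            class_counts[u.label.cls] = class_counts.get(u.label.cls, 0) + u.size
        manifest["stages"][stage] = {"class_protein_counts": class_counts}

        # --- comparative
        stage = "compare"
        matrix = comparative.count_matrix(l2, proteins, species)
        matrix.to_csv(outdir / "count_matrix.tsv", sep="\t",
                      index_label="cluster_id")
        subset = comparative.lhca_subset(matrix, species)
        estimates, lhca_total = comparative.lhca_proteome(
            matrix, subset, species,
            include_zero_outgroup=config.lhca_include_zero_outgroup)
        io_formats._write_tsv(
            outdir / "lhca_proteome.tsv",
            ["cluster_id", "outgroup1", "outgroup2", "estimate", "class"],
            ((e.cluster_id, e.c_out1, e.c_out2, e.estimate,
              l2_labels[e.cluster_id].cls) for e in estimates))
        inno = comparative.innovation_classes(matrix, species)
        io_formats._write_tsv(
            outdir / "innovation_report.tsv", ["cluster_id", "category"],
            [(cid, "lhca") for cid in inno.lhca]
            + [(cid, "metazoan_innovation") for cid in inno.metazoan_innovation]
            + [(cid, "species_specific") for cid in inno.species_specific]
            + [(cid, "other") for cid in inno.other])
        if matrix.shape[1] >= 2 and len(subset) > 0:
            z, flagged = comparative.standardize(matrix, subset)
            z.round(4).to_csv(outdir / "standardized_matrix.tsv", sep="\t",
                              index_label="cluster_id")
        per_species = pd.DataFrame(
            {"total": [s.total for s in summaries],
             "membrane": [s.membrane for s in summaries]},
            index=[s.species_id for s in summaries])
        summary = (comparative.summary_statistics(per_species, class_counts)
                   if len(per_species) >= 3 else None)
        manifest["stages"][stage] = {
            "lhca_clusters": len(subset), "lhca_proteome_total": lhca_total,
            "metazoan_innovation": len(inno.metazoan_innovation),
            "species_specific": len(inno.species_specific)}
        if summary is not None:
            manifest["stages"][stage]["rho_membrane_vs_total"] = \
                summary.rho_membrane_vs_total
            manifest["stages"][stage]["percent_classified"] = \
                summary.percent_classified
    except HolomemError as exc:
        raise DataError(f"stage '{stage}' failed: {exc}") from exc

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")

    return RunResult(outdir, proteins, membrane_proteins, summaries, l1, l2,
                     l1_labels, l2_labels, matrix, manifest)


def report(outdir: str | Path) -> str:
    """Human-readable run summary rendered from the stage tables only."""
    outdir = Path(outdir)
    manifest_path = outdir / "manifest.json"
    if not manifest_path.exists():
        raise DataError(f"incomplete run: {manifest_path} missing")
    manifest = json.loads(manifest_path.read_text())
    mem = pd.read_csv(outdir / "membrane_summary.tsv", sep="\t")
    lines = ["Membrane proteome per species", "-" * 46]
    for row in mem.itertuples(index=False):
        lines.append(f"{row.species:<16} total {row.total:>6} membrane "
                     f"{row.membrane:>6} ({row.percent}%)")
    total = int(mem["total"].sum())
    lines.append(f"{'ALL':<16} total {total:>6} membrane "
                 f"{int(mem['membrane'].sum()):>6}"
                 + (f" ({integer_percent(mem['membrane'].sum(), total)}%)"
                    if total else ""))
    cmp_stage = manifest["stages"].get("compare", {})
    cls_stage = manifest["stages"].get("classify", {})
    lines.append("")
    lines.append("Cluster categories")
    lines.append("-" * 46)
    for key in ("lhca_clusters", "lhca_proteome_total", "metazoan_innovation",
                "species_specific", "rho_membrane_vs_total",
                "percent_classified"):
        if key in cmp_stage:
            lines.append(f"{key:<26} {cmp_stage[key]}")
    counts = cls_stage.get("class_protein_counts", {})
    if counts:
        lines.append("")
        lines.append("Functional class protein counts")
        lines.append("-" * 46)
        for cls, n in sorted(counts.items()):
            lines.append(f"{cls:<26} {n}")
    return "\n".join(lines) + "\n"
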