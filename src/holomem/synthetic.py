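"""Synthetic input bundles with planted family structure.

The generator emits a complete, internally consistent input set — per
species FASTA with multi-isoform genes, all-vs-all tabular BLAST hits,
a Pfam-scan-style annotation table, a topology/signal-peptide table,
species metadata and human-proxy functional annotations — together with
the ground truth needed to score recovery: which planted family each
protein belongs to, each family's presence pattern, functional class
and per-species copy numbers.

Three presence patterns are planted:

* ``lhca_conserved`` — present in at least one unicellular outgroup and
  in metazoans (the ancestral families);
* ``metazoan_novel`` — absent from both outgroups, present in at least
  two metazoan species;
* ``species_specific`` — confined to exactly one species.

Sequences are random amino-acid strings: no pipeline stage reads
residues except through lengths, so only lengths and identifiers are
semantically meaningful. E-values are drawn log-uniformly; within-family
hits sit strictly below the 0.01 threshold while spurious cross-family
hits may straddle it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import numpy as np
import yaml

from .errors import ConfigurationError
from .io_formats import (
    FastaProtein,
    write_fasta,
    write_hits_m8,
    write_human_annotations,
    write_pfam,
    write_pfam_class_map,
    write_species,
    write_topology,
)
from .records import (
    INVERTEBRATE,
    OUTGROUP,
    VERTEBRATE,
    FamilyAnnotation,
    HumanAnnotation,
    SpeciesInfo,
)

PATTERNS = ("lhca_conserved", "metazoan_novel", "species_specific")
CLASSES = ("enzyme", "transporter", "receptor", "other", "DUF", "none")

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def default_species() -> list[SpeciesInfo]:
    """A 24-species roster: 2 unicellular outgroups, 5 vertebrates (one
    human proxy) and 17 invertebrates, mirroring the published survey's
    taxon sampling."""
    vertebrates = ["vrt_hsap", "vrt_mmus", "vrt_ggal", "vrt_xtro", "vrt_drer"]
    invertebrates = [
        "inv_cint", "inv_spur", "inv_dmel", "inv_amel", "inv_apis", "inv_dpul",
        "inv_cele", "inv_ctel", "inv_lana", "inv_cgig", "inv_lgig", "inv_ilin",
        "inv_sman", "inv_nvec", "inv_tadh", "inv_mlei", "inv_aque",
    ]
    roster = [SpeciesInfo("out_mbre", OUTGROUP), SpeciesInfo("out_cowc", OUTGROUP)]
    roster += [SpeciesInfo(s, VERTEBRATE, is_human_proxy=(s == "vrt_hsap"))
               for s in vertebrates]
    roster += [SpeciesInfo(s, INVERTEBRATE) for s in invertebrates]
    return roster


def default_patterns(n_lhca: int = 40, n_novel: int = 15,
                     n_specific: int = 5) -> tuple[str, ...]:
    return (("lhca_conserved",) * n_lhca + ("metazoan_novel",) * n_novel
            + ("species_specific",) * n_specific)


@dataclass
class SimulationConfig:
    seed: int = 1
    species: list[SpeciesInfo] = field(default_factory=default_species)
    patterns: tuple[str, ...] = field(default_factory=default_patterns)
    mean_copy_number: float = 1.8
    clade_multipliers: dict[str, float] = field(default_factory=lambda: {
        OUTGROUP: 1.0, INVERTEBRATE: 1.2, VERTEBRATE: 2.0})
    outgroup_presence: float = 0.9
    metazoan_presence: float = 0.95
    novel_presence: float = 0.6
    annot_rate: float = 0.9
    domain_only_fraction: float = 0.2
    within_family_log10e: tuple[float, float] = (-180.0, -20.0)
    spurious_rate: float = 2e-5
    spurious_log10e: tuple[float, float] = (-4.0, 1.0)
    isoform_probs: tuple[float, ...] = (0.6, 0.3, 0.1)  # P(1, 2, 3 isoforms)
    membrane_fraction: float = 1.0
    class_probs: dict[str, float] = field(default_factory=lambda: {
        "enzyme": 0.20, "transporter": 0.20, "receptor": 0.25,
        "other": 0.20, "DUF": 0.08, "none": 0.07})
    #: Optional exact copy-number override: family index -> species -> count.
    fixed_counts: dict[int, dict[str, int]] | None = None

    @property
    def n_families(self) -> int:
        return len(self.patterns)

    def validate(self) -> None:
        sp_ids = [s.species_id for s in self.species]
        if not sp_ids:
            raise ConfigurationError("species", "at least one species required")
        if len(set(sp_ids)) != len(sp_ids):
            raise ConfigurationError("species", "duplicate species ids")
        if sum(s.is_human_proxy for s in self.species) != 1:
            raise ConfigurationError("species", "exactly one human-proxy species "
                                                "required")
        n_out = sum(s.is_outgroup for s in self.species)
        needs_outgroups = any(p == "lhca_conserved" for p in self.patterns)
        if needs_outgroups and n_out != 2:
            raise ConfigurationError(
                "species", f"lhca_conserved families need exactly 2 outgroup "
                           f"species, found {n_out}")
        n_meta = len(sp_ids) - n_out
        if any(p == "metazoan_novel" for p in self.patterns) and n_meta < 2:
            raise ConfigurationError(
                "species", "metazoan_novel families need >= 2 metazoan species")
        for p in self.patterns:
            if p not in PATTERNS:
                raise ConfigurationError("patterns", f"unknown pattern {p!r}")
        if not self.patterns:
            raise ConfigurationError("patterns", "at least one family required")
        for name in ("outgroup_presence", "metazoan_presence", "novel_presence",
                     "annot_rate", "domain_only_fraction", "membrane_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(name, f"rate {v} outside [0, 1]")
        if self.spurious_rate < 0 or self.spurious_rate > 1:
            raise ConfigurationError("spurious_rate", "outside [0, 1]")
        lo, hi = self.within_family_log10e
        if lo > hi:
            raise ConfigurationError("within_family_log10e", "interval reversed")
        if hi >= math.log10(0.01):
            raise ConfigurationError(
                "within_family_log10e",
                "interval must lie strictly below log10(0.01) = -2")
        if self.spurious_log10e[0] > self.spurious_log10e[1]:
            raise ConfigurationError("spurious_log10e", "interval reversed")
        if abs(sum(self.isoform_probs) - 1.0) > 1e-9 or \
                any(p < 0 for p in self.isoform_probs):
            raise ConfigurationError("isoform_probs", "must be a distribution")
        if abs(sum(self.class_probs.values()) - 1.0) > 1e-9:
            raise ConfigurationError("class_probs", "must sum to 1")
        if set(self.class_probs) - set(CLASSES):
            raise ConfigurationError("class_probs",
                                     f"unknown classes {set(self.class_probs) - set(CLASSES)}")
        if self.mean_copy_number <= 0:
            raise ConfigurationError("mean_copy_number", "must be > 0")


@dataclass
class GroundTruth:
    protein_to_family: dict[str, int]
    family_pattern: dict[int, str]
    family_class: dict[int, str]
    family_counts: dict[int, dict[str, int]]  # only species with count > 0
    family_membrane: dict[int, bool]
    family_pfam: dict[int, tuple[str, str, str] | None]  # (acc, name, model_type)

    @property
    def n_proteins(self) -> int:
        return len(self.protein_to_family)


def truth_count_matrix(truth: GroundTruth, species: list[SpeciesInfo] | None = None):
    """Planted family-by-species copy-number matrix."""
    import pandas as pd

    if species is not None:
        columns = [s.species_id for s in species]
    else:
        columns = sorted({sp for c in truth.family_counts.values() for sp in c})
    rows = {fam: {sp: counts.get(sp, 0) for sp in columns}
            for fam, counts in sorted(truth.family_counts.items())}
    return pd.DataFrame.from_dict(rows, orient="index", dtype=int,
                                  columns=columns)


@dataclass
class BundlePaths:
    root: Path

    @property
    def fasta_dir(self) -> Path:
        return self.root / "fasta"

    @property
    def hits(self) -> Path:
        return self.root / "hits.m8"

    @property
    def pfam(self) -> Path:
        return self.root / "pfam.tsv"

    @property
    def topology(self) -> Path:
        return self.root / "topology.tsv"

    @property
    def species(self) -> Path:
        return self.root / "species.tsv"

    @property
    def human_annotations(self) -> Path:
        return self.root / "human_annotations.tsv"

    @property
    def pfam_class_map(self) -> Path:
        return self.root / "pfam_class_map.tsv"

    @property
    def truth_dir(self) -> Path:
        return self.root / "truth"

    @property
    def config_file(self) -> Path:
        return self.root / "config.yaml"

    def fasta_for(self, species_id: str) -> Path:
        return self.fasta_dir / f"{species_id}.fasta"


def generate_bundle(config: SimulationConfig,
                    outdir: str | Path) -> tuple[BundlePaths, GroundTruth]:
    """Write a full synthetic bundle under ``outdir``; deterministic in seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    outdir = Path(outdir)
    paths = BundlePaths(outdir)
    paths.fasta_dir.mkdir(parents=True, exist_ok=True)
    paths.truth_dir.mkdir(parents=True, exist_ok=True)

    families = _plant_families(config, rng)
    proteins, truth = _emit_proteins(config, families, rng)

    _write_fastas(config, proteins, paths)
    _write_topology(proteins, paths, rng)
    hits = _emit_hits(config, proteins, truth, rng)
    write_hits_m8(hits, paths.hits)
    _write_pfam(config, proteins, truth, paths, rng)
    write_species(config.species, paths.species)
    _write_human_annotations(config, proteins, truth, paths)
    _write_class_map(truth, paths)
    _write_truth(truth, config, paths)
    _write_config(config, paths)
    return paths, truth


# ---------------------------------------------------------------------------
# planting


@dataclass
class _Family:
    index: int
    pattern: str
    fclass: str
    membrane: bool
    pfam: tuple[str, str, str] | None  # accession, model name, model type
    base_length: int
    counts: dict[str, int]  # species -> copies (> 0 entries only)


def _plant_families(config: SimulationConfig, rng) -> list[_Family]:
    classes = sorted(config.class_probs)
    probs = np.array([config.class_probs[c] for c in classes])
    out = []
    for f, pattern in enumerate(config.patterns):
        fclass = classes[rng.choice(len(classes), p=probs)]
        membrane = bool(rng.random() < config.membrane_fraction)
        if fclass == "none":
            pfam = None
        else:
            acc = f"PF{10000 + f:05d}"
            name = f"DUF{1000 + f:04d}" if fclass == "DUF" else f"SynFam{f:03d}"
            mtype = "Domain" if rng.random() < config.domain_only_fraction \
                else "Family"
            pfam = (acc, name, mtype)
        base_length = int(rng.integers(250, 701))
        counts = _plant_counts(config, pattern, rng)
        out.append(_Family(f, pattern, fclass, membrane, pfam, base_length,
                           counts))
    return out


def _copies(config: SimulationConfig, clade: str, rng) -> int:
    mean = config.mean_copy_number * config.clade_multipliers.get(clade, 1.0)
    return max(1, int(rng.poisson(mean)))


def _plant_counts(config: SimulationConfig, pattern: str, rng) -> dict[str, int]:
    if config.fixed_counts is not None:
        # exact override path is resolved in _plant_families caller per family
        pass
    outgroups = [s for s in config.species if s.is_outgroup]
    metazoans = [s for s in config.species if not s.is_outgroup]
    counts: dict[str, int] = {}
    if pattern == "lhca_conserved":
        present_out = [s for s in outgroups
                       if rng.random() < config.outgroup_presence]
        if not present_out:
            present_out = [outgroups[int(rng.integers(len(outgroups)))]]
        present_met = [s for s in metazoans
                       if rng.random() < config.metazoan_presence]
        if not present_met:
            present_met = [metazoans[int(rng.integers(len(metazoans)))]]
        for s in present_out + present_met:
            counts[s.species_id] = _copies(config, s.clade, rng)
    elif pattern == "metazoan_novel":
        present = [s for s in metazoans if rng.random() < config.novel_presence]
        while len(present) < 2:
            extra = metazoans[int(rng.integers(len(metazoans)))]
            if extra not in present:
                present.append(extra)
        for s in sorted(present, key=lambda s: s.species_id):
            counts[s.species_id] = _copies(config, s.clade, rng)
    else:  # species_specific
        s = config.species[int(rng.integers(len(config.species)))]
        counts[s.species_id] = _copies(config, s.clade, rng)
    return counts


# ---------------------------------------------------------------------------
# proteins, sequences, files


@dataclass
class _Protein:
    protein_id: str
    gene_id: str
    species_id: str
    family: int
    length: int
    canonical: bool
    membrane: bool


def _emit_proteins(config: SimulationConfig, families: list[_Family],
                   rng) -> tuple[list[_Protein], GroundTruth]:
    proteins: list[_Protein] = []
    protein_to_family: dict[str, int] = {}
    family_counts: dict[int, dict[str, int]] = {}
    n_iso_choices = np.arange(1, len(config.isoform_probs) + 1)
    for fam in families:
        counts = (dict(config.fixed_counts.get(fam.index, {}))
                  if config.fixed_counts is not None else fam.counts)
        counts = {sp: c for sp, c in counts.items() if c > 0}
        fam.counts = counts
        family_counts[fam.index] = counts
        for sp_id in (s.species_id for s in config.species):
            c = counts.get(sp_id, 0)
            for k in range(c):
                gene = f"{sp_id}_F{fam.index:03d}g{k:02d}"
                n_iso = int(rng.choice(n_iso_choices,
                                       p=np.asarray(config.isoform_probs)))
                can_len = max(60, int(fam.base_length
                                      * (0.9 + 0.2 * rng.random())))
                for i in range(n_iso):
                    if i == 0:
                        length, canonical = can_len, True
                    else:
                        length = can_len - int(rng.integers(10, can_len - 50))
                        length = max(50, length)
                        canonical = False
                    pid = f"{gene}p{i}"
                    proteins.append(_Protein(pid, gene, sp_id, fam.index,
                                             length, canonical, fam.membrane))
                    if canonical:
                        protein_to_family[pid] = fam.index
    truth = GroundTruth(
        protein_to_family=protein_to_family,
        family_pattern={f.index: f.pattern for f in families},
        family_class={f.index: f.fclass for f in families},
        family_counts=family_counts,
        family_membrane={f.index: f.membrane for f in families},
        family_pfam={f.index: f.pfam for f in families},
    )
    return proteins, truth


def _random_sequence(length: int, rng) -> str:
    return "".join(AMINO_ACIDS[rng.integers(0, len(AMINO_ACIDS), size=length)])


def _write_fastas(config: SimulationConfig, proteins: list[_Protein],
                  paths: BundlePaths) -> None:
    seq_rng = np.random.default_rng(config.seed + 10_007)
    by_species: dict[str, list[FastaProtein]] = {
        s.species_id: [] for s in config.species}
    for p in proteins:  # generation order is deterministic
        by_species[p.species_id].append(
            FastaProtein(p.protein_id, p.gene_id, p.species_id,
                         _random_sequence(p.length, seq_rng)))
    for sp_id, records in by_species.items():
        write_fasta(records, paths.fasta_for(sp_id))


def _write_topology(proteins: list[_Protein], paths: BundlePaths, rng) -> None:
    rows: dict[str, tuple[int, bool, int | None]] = {}
    gene_topology: dict[str, tuple[int, bool, int | None]] = {}
    for p in proteins:
        if p.gene_id not in gene_topology:
            tm = int(rng.integers(1, 13)) if p.membrane else 0
            has_sp = bool(rng.random() < 0.3)
            cut = int(rng.integers(15, 36)) if has_sp else None
            gene_topology[p.gene_id] = (tm, has_sp, cut)
        rows[p.protein_id] = gene_topology[p.gene_id]
    write_topology(rows, paths.topology)


def _m8_row(q: _Protein, s: _Protein, evalue: float, rng) -> list:
    aln = min(q.length, s.length)
    pident = round(30 + 65 * rng.random(), 1)
    mismatch = int(aln * (100 - pident) / 100)
    bitscore = round(max(20.0, -2.0 * math.log10(evalue)
                         if evalue > 0 else 500.0), 1)
    return [q.protein_id, s.protein_id, pident, aln, mismatch, 0,
            1, aln, 1, aln, f"{evalue:.3g}", bitscore]


def _emit_hits(config: SimulationConfig, proteins: list[_Protein],
               truth: GroundTruth, rng) -> list[list]:
    canonical = [p for p in proteins if p.canonical]
    by_family: dict[int, list[_Protein]] = {}
    for p in canonical:
        by_family.setdefault(p.family, []).append(p)
    lo, hi = config.within_family_log10e
    rows: list[list] = []
    for fam in sorted(by_family):
        members = by_family[fam]
        for i, q in enumerate(members):
            for j, s in enumerate(members):
                if i == j:
                    continue
                evalue = float(10.0 ** rng.uniform(lo, hi))
                rows.append(_m8_row(q, s, evalue, rng))
    # spurious cross-family noise
    n = len(canonical)
    sizes = np.array([len(v) for v in by_family.values()])
    n_cross = n * (n - 1) - int((sizes * (sizes - 1)).sum())
    if n_cross > 0 and config.spurious_rate > 0:
        n_spur = int(rng.poisson(config.spurious_rate * n_cross))
        slo, shi = config.spurious_log10e
        emitted = 0
        while emitted < n_spur:
            qi, si = rng.integers(0, n, size=2)
            q, s = canonical[int(qi)], canonical[int(si)]
            if q.family == s.family:
                continue
            evalue = float(10.0 ** rng.uniform(slo, shi))
            rows.append(_m8_row(q, s, evalue, rng))
            emitted += 1
    return rows


def _write_pfam(config: SimulationConfig, proteins: list[_Protein],
                truth: GroundTruth, paths: BundlePaths, rng) -> None:
    annotations: list[FamilyAnnotation] = []
    for p in proteins:
        if not p.canonical:
            continue
        pfam = truth.family_pfam[p.family]
        if pfam is None:
            continue
        if rng.random() < config.annot_rate:
            acc, name, mtype = pfam
            annotations.append(FamilyAnnotation(p.protein_id, acc, name, mtype))
    write_pfam(annotations, paths.pfam)


def _write_human_annotations(config: SimulationConfig, proteins: list[_Protein],
                             truth: GroundTruth, paths: BundlePaths) -> None:
    proxy = next(s.species_id for s in config.species if s.is_human_proxy)
    # deterministic per-family EC / TCDB identifiers, derived from the index
    anns: list[HumanAnnotation] = []
    for p in proteins:
        if not p.canonical or p.species_id != proxy:
            continue
        fclass = truth.family_class[p.family]
        f = p.family
        if fclass == "enzyme":
            ec = f"{1 + f % 6}.{1 + f % 9}.{1 + f % 20}.-"
            anns.append(HumanAnnotation(p.protein_id, ec_number=ec))
        elif fclass == "transporter":
            tcdb = f"{1 + f % 9}.A.{1 + f % 30}"
            anns.append(HumanAnnotation(p.protein_id, tcdb_id=tcdb))
        elif fclass in ("receptor", "other"):
            anns.append(HumanAnnotation(
                p.protein_id, curated_class=fclass,
                function_summary=f"synthetic family {f} ({fclass})"))
        # DUF / none: no human-proxy functional record
    write_human_annotations(anns, paths.human_annotations)


def _write_class_map(truth: GroundTruth, paths: BundlePaths) -> None:
    mapping = {}
    for fam, pfam in sorted(truth.family_pfam.items()):
        if pfam is None:
            continue
        fclass = truth.family_class[fam]
        if fclass in ("enzyme", "transporter", "receptor", "other"):
            mapping[pfam[0]] = fclass
    write_pfam_class_map(mapping, paths.pfam_class_map)


def _write_truth(truth: GroundTruth, config: SimulationConfig,
                 paths: BundlePaths) -> None:
    from .io_formats import _write_tsv  # shared TSV writer

    _write_tsv(paths.truth_dir / "protein_families.tsv",
               ["protein_id", "family"],
               sorted(truth.protein_to_family.items()))
    _write_tsv(paths.truth_dir / "families.tsv",
               ["family", "pattern", "functional_class", "is_membrane",
                "pfam_accession", "model_type"],
               ((f, truth.family_pattern[f], truth.family_class[f],
                 int(truth.family_membrane[f]),
                 truth.family_pfam[f][0] if truth.family_pfam[f] else "",
                 truth.family_pfam[f][2] if truth.family_pfam[f] else "")
                for f in sorted(truth.family_pattern)))
    _write_tsv(paths.truth_dir / "family_counts.tsv",
               ["family", "species", "count"],
               ((f, sp, c) for f in sorted(truth.family_counts)
                for sp, c in sorted(truth.family_counts[f].items())))


def _write_config(config: SimulationConfig, paths: BundlePaths) -> None:
    data = asdict(config)
    data["species"] = [[s.species_id, s.clade, int(s.is_human_proxy)]
                       for s in config.species]
    data["patterns"] = list(config.patterns)
    data["isoform_probs"] = list(config.isoform_probs)
    data["within_family_log10e"] = list(config.within_family_log10e)
    data["spurious_log10e"] = list(config.spurious_log10e)
    with open(paths.config_file, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def load_truth(paths: BundlePaths) -> GroundTruth:
    """Re-read a bundle's ground-truth tables."""
    import pandas as pd

    pf = pd.read_csv(paths.truth_dir / "protein_families.tsv", sep="\t")
    fams = pd.read_csv(paths.truth_dir / "families.tsv", sep="\t",
                       keep_default_na=False)
    counts = pd.read_csv(paths.truth_dir / "family_counts.tsv", sep="\t")
    family_counts: dict[int, dict[str, int]] = {
        int(f): {} for f in fams["family"]}
    for fam, sp, c in counts.itertuples(index=False, name=None):
        family_counts[int(fam)][str(sp)] = int(c)
    return GroundTruth(
        protein_to_family={str(r.protein_id): int(r.family)
                           for r in pf.itertuples(index=False)},
        family_pattern={int(r.family): str(r.pattern)
                        for r in fams.itertuples(index=False)},
        family_class={int(r.family): str(r.functional_class)
                      for r in fams.itertuples(index=False)},
        family_counts=family_counts,
        family_membrane={int(r.family): bool(r.is_membrane)
                         for r in fams.itertuples(index=False)},
        family_pfam={int(r.family):
                     ((str(r.pfam_accession), "", str(r.model_type))
                      if r.pfam_accession else None)
                     for r in fams.itertuples(index=False)},
    )
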