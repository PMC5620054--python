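"""Readers and writers for every external format the pipeline touches.

Dialects
--------
* FASTA headers follow one canonical dialect ``proteinID|geneID`` (the
  many source-database header styles are normalised to this before the
  pipeline runs; the parser is pluggable via ``header_parser``).
* BLAST hits are tabular outfmt-6: 12 tab-separated columns, e-value in
  column 11, no header line.
* All other tables are tab-separated UTF-8 with one header line.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import DataError, ParseError
from .records import (
    CLADES,
    MODEL_TYPES,
    Cluster,
    FamilyAnnotation,
    FunctionalLabel,
    HumanAnnotation,
    ProteinRecord,
    SpeciesInfo,
)

logger = logging.getLogger(__name__)

M8_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def parse_pipe_header(header: str) -> tuple[str, str]:
    """Parse the canonical ``proteinID|geneID`` header (strict)."""
    parts = header.split("|")
    if len(parts) != 2 or not parts[0] or not parts[1]:
        raise ValueError(f"header {header!r} does not match 'proteinID|geneID'")
    return parts[0], parts[1]


@dataclass
class FastaProtein:
    """A FASTA record plus its parsed identity; only the length is used
    downstream of the isoform filter."""

    protein_id: str
    gene_id: str
    species_id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)

    def to_record(self) -> ProteinRecord:
        return ProteinRecord(
            protein_id=self.protein_id,
            gene_id=self.gene_id,
            species_id=self.species_id,
            length=self.length,
        )


def _header_lines(path: Path) -> list[int]:
    """1-based line numbers of FASTA header lines, for parse diagnostics."""
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if line.startswith(">"):
                out.append(i)
    return out


def read_fasta(
    path: str | Path,
    species_id: str,
    header_parser: Callable[[str], tuple[str, str]] = parse_pipe_header,
) -> list[FastaProtein]:
    """Read one species FASTA into :class:`FastaProtein` records.

    An empty file yields an empty list (logged as a warning, since a
    species with no proteins is almost always an input mistake).
    """
    path = Path(path)
    lines = _header_lines(path)
    out: list[FastaProtein] = []
    for lineno, rec in zip(lines, SeqIO.parse(str(path), "fasta")):
        try:
            protein_id, gene_id = header_parser(rec.id)
        except ValueError as exc:
            raise ParseError(str(exc), path=path, line=lineno) from exc
        if len(rec.seq) == 0:
            raise ParseError(f"empty sequence for {rec.id}", path=path, line=lineno)
        out.append(FastaProtein(protein_id, gene_id, species_id, str(rec.seq)))
    if not out:
        logger.warning("FASTA %s contained no records", path)
    return out


def write_fasta(proteins: Iterable[FastaProtein], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(p.sequence), id=f"{p.protein_id}|{p.gene_id}", description="")
        for p in proteins
    ]
    SeqIO.write(records, str(path), "fasta")


def select_longest_isoform(proteins: Iterable) -> list:
    """Keep the longest isoform per gene.

    Ties are broken by the lexicographically smallest protein id so the
    result is independent of input order. Works on any objects exposing
    ``gene_id``, ``protein_id`` and ``length``.
    """
    best: dict[str, object] = {}
    for p in proteins:
        cur = best.get(p.gene_id)
        if cur is None or (p.length, _neg_id(p)) > (cur.length, _neg_id(cur)):
            best[p.gene_id] = p
    return sorted(best.values(), key=lambda p: p.protein_id)


class _neg_id:
    """Ordering adaptor: higher priority for the smaller protein id."""

    __slots__ = ("pid",)

    def __init__(self, p):
        self.pid = p.protein_id

    def __lt__(self, other):
        return self.pid > other.pid

    def __gt__(self, other):
        return self.pid < other.pid

    def __eq__(self, other):
        return self.pid == other.pid


def filter_by_allowlist(proteins: Iterable, allowlist: set[str] | None) -> list:
    """Optional identifier-support filter (off when ``allowlist`` is None)."""
    if allowlist is None:
        return list(proteins)
    return [p for p in proteins if p.protein_id in allowlist]


# ---------------------------------------------------------------------------
# BLAST tabular hits


def read_hits(path: str | Path, max_evalue: float = 0.01) -> list:
    """Read outfmt-6 hits, dropping self-hits and rows above ``max_evalue``.

    An e-value of exactly 0 is kept verbatim; the cap is applied later at
    the weight transform, not at parse time.
    """
    from .records import SimilarityHit

    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=M8_COLUMNS,
                         dtype={"qseqid": str, "sseqid": str, "evalue": str})
    except pd.errors.EmptyDataError:
        logger.warning("hit table %s is empty", path)
        return []
    if df.shape[1] != 12:
        raise ParseError(f"expected 12 columns, found {df.shape[1]}", path=path)
    evalue = pd.to_numeric(df["evalue"], errors="coerce")
    bad = evalue.isna()
    if bad.any():
        lineno = int(bad.idxmax()) + 1
        raise ParseError(
            f"non-numeric e-value {df['evalue'][bad.idxmax()]!r}", path=path, line=lineno
        )
    total = len(df)
    self_mask = df["qseqid"] == df["sseqid"]
    keep = (~self_mask) & (evalue <= max_evalue)
    dropped = int(total - keep.sum())
    logger.info("read %d hit rows from %s, dropped %d (self or e > %g)",
                total, path, dropped, max_evalue)
    return [
        SimilarityHit(q, s, float(e))
        for q, s, e in zip(df["qseqid"][keep], df["sseqid"][keep], evalue[keep])
    ]


def write_hits_m8(rows: Iterable[Iterable], path: str | Path) -> None:
    """Write pre-built 12-column outfmt-6 rows."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for row in rows:
            writer.writerow(row)


# ---------------------------------------------------------------------------
# Annotation / metadata tables


def read_pfam(path: str | Path) -> list[FamilyAnnotation]:
    path = Path(path)
    df = _read_tsv(path, ["protein_id", "pfam_accession", "model_name", "model_type"])
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        if row.model_type not in MODEL_TYPES:
            raise ParseError(f"unknown model_type {row.model_type!r}", path=path, line=i)
        out.append(FamilyAnnotation(str(row.protein_id), str(row.pfam_accession),
                                    str(row.model_name), str(row.model_type)))
    return out


def write_pfam(annotations: Iterable[FamilyAnnotation], path: str | Path) -> None:
    _write_tsv(path, ["protein_id", "pfam_accession", "model_name", "model_type"],
               ((a.protein_id, a.pfam_accession, a.model_name, a.model_type)
                for a in annotations))


def read_topology(path: str | Path) -> dict[str, tuple[int, bool, int | None]]:
    """Per-protein topology facts: ``protein_id -> (tm_count, has_sp, cut_site)``."""
    path = Path(path)
    df = _read_tsv(path, ["protein_id", "tm_count", "has_signal_peptide",
                          "signal_cut_site"])
    out = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            tm = int(row.tm_count)
            sp = bool(int(row.has_signal_peptide))
            cut = None if pd.isna(row.signal_cut_site) or row.signal_cut_site == "" \
                else int(row.signal_cut_site)
        except (TypeError, ValueError) as exc:
            raise ParseError(f"bad topology row: {exc}", path=path, line=i) from exc
        if tm < 0:
            raise ParseError("negative TM count", path=path, line=i)
        out[str(row.protein_id)] = (tm, sp, cut)
    return out


def write_topology(rows: dict[str, tuple[int, bool, int | None]],
                   path: str | Path) -> None:
    _write_tsv(path, ["protein_id", "tm_count", "has_signal_peptide",
                      "signal_cut_site"],
               ((pid, tm, int(sp), "" if cut is None else cut)
                for pid, (tm, sp, cut) in rows.items()))


def read_species(path: str | Path) -> list[SpeciesInfo]:
    path = Path(path)
    df = _read_tsv(path, ["species_id", "clade", "is_human_proxy"])
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        if row.clade not in CLADES:
            raise ParseError(f"unknown clade {row.clade!r}", path=path, line=i)
        out.append(SpeciesInfo(str(row.species_id), str(row.clade),
                               bool(int(row.is_human_proxy))))
    return out


def write_species(species: Iterable[SpeciesInfo], path: str | Path) -> None:
    _write_tsv(path, ["species_id", "clade", "is_human_proxy"],
               ((s.species_id, s.clade, int(s.is_human_proxy)) for s in species))


def read_human_annotations(path: str | Path) -> dict[str, HumanAnnotation]:
    path = Path(path)
    df = _read_tsv(path, ["protein_id", "ec_number", "tcdb_id", "curated_class",
                          "function_summary"])
    out = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        curated = _opt(row.curated_class)
        if curated is not None and curated not in ("receptor", "other"):
            raise ParseError(f"curated_class must be receptor/other, got {curated!r}",
                             path=path, line=i)
        ann = HumanAnnotation(str(row.protein_id), _opt(row.ec_number),
                              _opt(row.tcdb_id), curated, _opt(row.function_summary))
        out[ann.protein_id] = ann
    return out


def write_human_annotations(anns: Iterable[HumanAnnotation], path: str | Path) -> None:
    _write_tsv(path, ["protein_id", "ec_number", "tcdb_id", "curated_class",
                      "function_summary"],
               ((a.protein_id, a.ec_number or "", a.tcdb_id or "",
                 a.curated_class or "", a.function_summary or "") for a in anns))


def read_pfam_class_map(path: str | Path) -> dict[str, str]:
    """Pfam accession -> functional class, for clusters with no proxy member."""
    df = _read_tsv(Path(path), ["pfam_accession", "functional_class"])
    return {str(r.pfam_accession): str(r.functional_class)
            for r in df.itertuples(index=False)}


def write_pfam_class_map(mapping: dict[str, str], path: str | Path) -> None:
    _write_tsv(path, ["pfam_accession", "functional_class"],
               sorted(mapping.items()))


# ---------------------------------------------------------------------------
# Cluster tables

_CLUSTER_COLUMNS = ["cluster_id", "level", "members", "member_cluster_ids",
                    "class", "subclass", "duf_flag", "annotated_singlet_flag",
                    "varied_pfam_flag"]


def write_clusters(clusters: Iterable[Cluster], path: str | Path) -> None:
    def rows():
        for c in clusters:
            lab = c.label
            yield (c.cluster_id, c.level, ",".join(c.members),
                   ",".join(c.member_cluster_ids),
                   lab.cls if lab else "", (lab.subclass or "") if lab else "",
                   int(lab.duf_flag) if lab else 0,
                   int(lab.annotated_singlet_flag) if lab else 0,
                   int(lab.varied_pfam_flag) if lab else 0)

    _write_tsv(path, _CLUSTER_COLUMNS, rows())


def read_clusters(path: str | Path) -> list[Cluster]:
    path = Path(path)
    df = _read_tsv(path, _CLUSTER_COLUMNS)
    out = []
    for row in df.itertuples(index=False):
        cls = _opt(row[4])
        label = None
        if cls is not None:
            label = FunctionalLabel(cls, subclass=_opt(row.subclass),
                                    duf_flag=bool(int(row.duf_flag)),
                                    annotated_singlet_flag=bool(
                                        int(row.annotated_singlet_flag)),
                                    varied_pfam_flag=bool(int(row.varied_pfam_flag)))
        out.append(Cluster(
            cluster_id=str(row.cluster_id), level=int(row.level),
            members=_split(row.members), member_cluster_ids=_split(row.member_cluster_ids),
            label=label))
    return out


# ---------------------------------------------------------------------------
# helpers


def _read_tsv(path: Path, expected_columns: list[str]) -> pd.DataFrame:
    if not path.exists():
        raise DataError(f"missing input table: {path}")
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                         na_values=[])
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=expected_columns)
    if list(df.columns) != expected_columns:
        raise ParseError(
            f"expected columns {expected_columns}, found {list(df.columns)}",
            path=path, line=1)
    return df


def _write_tsv(path: str | Path, columns: list[str], rows: Iterable) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(columns)
        for row in rows:
            writer.writerow(row)


def _opt(value) -> str | None:
    s = str(value)
    return s if s != "" else None


def _split(value) -> list[str]:
    s = str(value)
    return s.split(",") if s else []
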