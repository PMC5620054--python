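"""Core record types passed between pipeline stages.

These are deliberately light dataclasses: the heavy per-stage state
(count matrices, cluster graphs) lives in pandas / networkx containers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

OUTGROUP = "outgroup"
INVERTEBRATE = "metazoan-invertebrate"
VERTEBRATE = "metazoan-vertebrate"
CLADES = (OUTGROUP, INVERTEBRATE, VERTEBRATE)

#: Pfam profile categories as emitted by pfam_scan-style annotation.
MODEL_TYPES = ("Family", "Domain", "Repeat", "Motif", "Coiled-coil", "Disordered")


@dataclass(frozen=True)
class SpeciesInfo:
    species_id: str
    clade: str
    is_human_proxy: bool = False

    @property
    def is_outgroup(self) -> bool:
        return self.clade == OUTGROUP


@dataclass
class ProteinRecord:
    """One protein after header parsing; topology fields are attached later.

    ``tm_count`` is ``None`` until a topology table has been joined; a
    protein that never receives topology is excluded from the membrane
    proteome and listed in the skipped-report.
    """

    protein_id: str
    gene_id: str
    species_id: str
    length: int
    tm_count: int | None = None
    has_signal_peptide: bool = False
    signal_cut_site: int | None = None  # 1-based last residue of the peptide

    def __post_init__(self):
        if self.length < 1:
            raise ValueError(f"{self.protein_id}: length must be >= 1")


@dataclass
class MatureProtein:
    """A protein after signal-peptide excision bookkeeping."""

    record: ProteinRecord
    mature_length: int

    @property
    def protein_id(self) -> str:
        return self.record.protein_id


@dataclass(frozen=True)
class SimilarityHit:
    query_id: str
    subject_id: str
    evalue: float

    def __post_init__(self):
        if self.evalue < 0:
            raise ValueError(f"negative e-value for {self.query_id}->{self.subject_id}")


@dataclass(frozen=True)
class FamilyAnnotation:
    protein_id: str
    pfam_accession: str
    model_name: str
    model_type: str

    @property
    def is_duf(self) -> bool:
        """Domain of Unknown Function, recognised by the curated DUF name."""
        return self.model_name.startswith("DUF")

    @property
    def is_family_type(self) -> bool:
        return self.model_type == "Family"


@dataclass(frozen=True)
class HumanAnnotation:
    """Functional facts for one protein of the human-proxy species."""

    protein_id: str
    ec_number: str | None = None
    tcdb_id: str | None = None
    curated_class: str | None = None  # "receptor" | "other"
    function_summary: str | None = None


@dataclass
class FunctionalLabel:
    cls: str  # enzyme | transporter | receptor | other | ambiguous | no_description
    subclass: str | None = None
    duf_flag: bool = False
    annotated_singlet_flag: bool = False
    varied_pfam_flag: bool = False


MAIN_CLASSES = ("enzyme", "transporter", "receptor", "other")


@dataclass
class Cluster:
    """A cluster at either level; level-2 clusters carry their level-1 members."""

    cluster_id: str
    level: int
    members: list[str] = field(default_factory=list)  # protein ids, sorted
    member_cluster_ids: list[str] = field(default_factory=list)  # level 2 only
    label: FunctionalLabel | None = None

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def is_singlet(self) -> bool:
        return len(self.members) == 1
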