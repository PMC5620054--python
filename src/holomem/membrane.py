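"""Signal-peptide excision bookkeeping and the membrane-proteome definition.

Topology and signal-peptide predictions are consumed from input tables,
never computed: a protein belongs to the membrane proteome iff its table
reports at least one alpha-helical transmembrane segment, assessed after
the predicted signal peptide has been excised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import DataError
from .records import MatureProtein, ProteinRecord
from .stats import integer_percent


def excise_signal(record: ProteinRecord) -> MatureProtein:
    """Remove the predicted signal peptide from the length bookkeeping.

    The cut site is the 1-based last residue of the peptide, so the
    mature length is ``length - cut_site``. A cut site at or past the end
    would leave no mature protein and is a data error.
    """
    if not record.has_signal_peptide or record.signal_cut_site is None:
        return MatureProtein(record, record.length)
    cut = record.signal_cut_site
    if cut >= record.length:
        raise DataError(
            f"{record.protein_id}: signal-peptide cut site {cut} >= length "
            f"{record.length}")
    if cut < 1:
        raise DataError(f"{record.protein_id}: cut site must be >= 1, got {cut}")
    return MatureProtein(record, record.length - cut)


@dataclass
class MembraneSummary:
    species_id: str
    total: int
    membrane: int
    percent: int
    skipped: list[str] = field(default_factory=list)


def membrane_proteome(
    records: list[ProteinRecord], species_id: str = ""
) -> tuple[list[ProteinRecord], MembraneSummary]:
    """Partition records into membrane (tm_count >= 1) and the rest.

    Records with no topology fact (``tm_count is None``) are excluded and
    listed in the summary's skipped-report; they count towards neither
    total nor membrane.
    """
    membrane, skipped = [], []
    n_with_topology = 0
    for r in records:
        if r.tm_count is None:
            skipped.append(r.protein_id)
            continue
        n_with_topology += 1
        if r.tm_count >= 1:
            membrane.append(r)
    percent = (integer_percent(len(membrane), n_with_topology)
               if n_with_topology else 0)
    summary = MembraneSummary(species_id, n_with_topology, len(membrane),
                              percent, skipped)
    return membrane, summary
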