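"""Define each species' membrane proteome from the synthetic bundle.

Reads the per-species FASTA, keeps the longest isoform per gene, joins
the topology table, applies signal-peptide excision bookkeeping and
keeps proteins with at least one predicted transmembrane helix. Writes
the per-species summary table (total, membrane, integer percent).
"""

from pathlib import Path

from holomem import io_formats, membrane

BUNDLE = Path("results/analysis/bundle")
OUT = Path("results/analysis")


def main() -> None:
    species = io_formats.read_species(BUNDLE / "species.tsv")
    topology = io_formats.read_topology(BUNDLE / "topology.tsv")
    rows = []
    for sp in species:
        records = io_formats.read_fasta(BUNDLE / "fasta" / f"{sp.species_id}.fasta",
                                        sp.species_id)
        kept = io_formats.select_longest_isoform(records)
        proteins = []
        for rec in kept:
            pr = rec.to_record()
            topo = topology.get(pr.protein_id)
            if topo is not None:
                pr.tm_count, pr.has_signal_peptide, pr.signal_cut_site = topo
                membrane.excise_signal(pr)
            proteins.append(pr)
        _, summary = membrane.membrane_proteome(proteins, sp.species_id)
        rows.append(summary)
    OUT.mkdir(parents=True, exist_ok=True)
    io_formats._write_tsv(OUT / "membrane_summary.tsv",
                          ["species", "total", "membrane", "percent"],
                          ((s.species_id, s.total, s.membrane, s.percent)
                           for s in rows))
    total = sum(s.total for s in rows)
    mem = sum(s.membrane for s in rows)
    print(f"{len(rows)} species: {total} proteins after isoform filtering, "
          f"{mem} membrane proteins")
    print(f"membrane fraction ranges "
          f"{min(s.percent for s in rows)}%..{max(s.percent for s in rows)}% "
          f"-> results/analysis/membrane_summary.tsv")


if __name__ == "__main__":
    main()
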