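"""Recompute the published survey's table statistics from its printed counts.

The published 24-species survey table (shipped with the package as
plain data) gives per-species total and membrane protein counts; its
text reports dataset-wide classification totals. This script recomputes
the derived statistics with this package's own routines: the integer
membrane percentages, the Spearman correlation between membrane and
total proteome size, and the functional-class share arithmetic.
"""

from holomem.datasets import survey_reported_totals, survey_species_table
from holomem.stats import integer_percent, spearman_rho


def main() -> None:
    table = survey_species_table()
    rho = spearman_rho(table["total_proteins"].tolist(),
                       table["membrane_proteins"].tolist())
    print(f"membrane vs total proteome size, Spearman rho = {rho:.2f} "
          f"over {len(table)} species")
    for sp in ("M_musculus", "A_pisum"):
        t = int(table.at[sp, "total_proteins"])
        m = int(table.at[sp, "membrane_proteins"])
        print(f"  {sp:<12} {m}/{t} membrane = {integer_percent(m, t)}%")

    totals = survey_reported_totals()
    n_mem = totals["total_membrane_proteins"]
    n_char = totals["characterized_proteins"]
    print(f"characterized: {n_char}/{n_mem} = {integer_percent(n_char, n_mem)}%")
    print(f"in LHCA-conserved clusters: {totals['lhca_subset_proteins']}/{n_mem}"
          f" = {integer_percent(totals['lhca_subset_proteins'], n_mem)}%")
    print(f"receptor share: {integer_percent(totals['receptor_proteins'], n_char)}%"
          f"  transporter share: "
          f"{integer_percent(totals['transporter_proteins'], n_char)}%")
    lhca = totals["lhca_proteome_total"]
    print(f"LHCA proteome ({lhca} proteins): enzymes "
          f"{integer_percent(totals['lhca_enzyme_proteins'], lhca)}%, "
          f"transporters "
          f"{integer_percent(totals['lhca_transporter_proteins'], lhca)}%")


if __name__ == "__main__":
    main()
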