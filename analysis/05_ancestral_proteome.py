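"""Reconstruct the ancestral (LHCA) membrane proteome and call innovations.

Loads the cluster-by-species count matrix written by
03_cluster_families.py, extracts the LHCA subset (present in an
outgroup and in metazoans), estimates the ancestral proteome by
averaging the two outgroup counts (rounding up), partitions the
remaining clusters into metazoan innovations / species-specific /
other, and writes the row-standardised matrix used for heatmaps.
"""

from pathlib import Path

import pandas as pd

from holomem import comparative, io_formats
from holomem.synthetic import BundlePaths, load_truth

BUNDLE = Path("results/analysis/bundle")
RUN = Path("results/analysis/run")
OUT = Path("results/analysis")


def main() -> None:
    matrix = pd.read_csv(RUN / "count_matrix.tsv", sep="\t",
                         index_col="cluster_id")
    species = io_formats.read_species(BUNDLE / "species.tsv")
    truth = load_truth(BundlePaths(BUNDLE))

    subset = comparative.lhca_subset(matrix, species)
    estimates, total = comparative.lhca_proteome(matrix, subset, species)
    inno = comparative.innovation_classes(matrix, species)
    n_planted = sum(p == "lhca_conserved" for p in truth.family_pattern.values())
    print(f"LHCA subset: {len(subset)} clusters (planted lhca_conserved "
          f"families: {n_planted})")
    print(f"reconstructed LHCA membrane proteome: {total} proteins")
    print(f"metazoan innovations: {len(inno.metazoan_innovation)} clusters; "
          f"species-specific: {len(inno.species_specific)}; "
          f"other: {len(inno.other)}")

    z, flagged = comparative.standardize(matrix, subset)
    z.round(4).to_csv(OUT / "lhca_standardized.tsv", sep="\t",
                      index_label="cluster_id")
    print(f"standardised LHCA matrix ({len(subset)} rows, "
          f"{len(flagged)} zero-variance) -> results/analysis/lhca_standardized.tsv")


if __name__ == "__main__":
    main()
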