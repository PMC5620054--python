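"""Summarise the functional classification of the clustered proteome.

Reads the level-2 cluster table written by 03_cluster_families.py and
reports protein counts and integer shares per functional class, plus
how many planted class labels were recovered exactly.
"""

from collections import Counter
from pathlib import Path

from holomem import io_formats
from holomem.stats import integer_percent
from holomem.synthetic import BundlePaths, load_truth

BUNDLE = Path("results/analysis/bundle")
RUN = Path("results/analysis/run")


def main() -> None:
    units = io_formats.read_clusters(RUN / "level2_clusters.tsv")
    truth = load_truth(BundlePaths(BUNDLE))
    counts: Counter = Counter()
    for u in units:
        counts[u.label.cls if u.label else "no_description"] += u.size
    classified = {k: v for k, v in counts.items()
                  if k not in ("ambiguous", "no_description")}
    n_classified, n_total = sum(classified.values()), sum(counts.values())
    print(f"{n_classified} of {n_total} membrane proteins classified "
          f"({integer_percent(n_classified, n_total)}%)")
    for cls, n in sorted(counts.items()):
        share = (f"{integer_percent(n, n_classified)}% of classified"
                 if cls in classified else "unclassified")
        print(f"  {cls:<15} {n:>5}  ({share})")

    # planted-class agreement for units dominated by one planted family
    truth_class = {"DUF": "other"}  # DUF families classify as other+flag
    agree = total = 0
    for u in units:
        fams = {truth.protein_to_family[p] for p in u.members}
        if len(fams) != 1 or u.label is None:
            continue
        planted = truth.family_class[fams.pop()]
        if planted == "none":
            continue
        total += 1
        agree += u.label.cls == truth_class.get(planted, planted)
    print(f"class recovery on single-family units: {agree}/{total}")


if __name__ == "__main__":
    main()
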