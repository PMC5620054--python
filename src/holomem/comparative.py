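"""Comparative evolution of membrane-protein families.

Builds the cluster-by-species count matrix and derives from it:

* the LHCA subset — clusters present in at least one of the two
  unicellular outgroups and in at least one metazoan species;
* the reconstructed LHCA proteome — per cluster, the ceiling of the
  mean of the two outgroup counts, summed over the subset;
* innovation classes — metazoan innovations (no outgroup member, at
  least two metazoan species) and species-specific clusters (all
  members from a single species);
* row-standardised matrices (z-scores per family across species) for
  heatmap rendering;
* summary statistics: integer membrane percentages and the Spearman
  correlation between membrane and total proteome size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .errors import DataError
from .records import Cluster, ProteinRecord, SpeciesInfo
from .stats import integer_percent, spearman_rho


def count_matrix(
    units: list[Cluster],
    proteins: list[ProteinRecord],
    species: list[SpeciesInfo],
) -> pd.DataFrame:
    """Cluster-by-species member counts (rows ordered by cluster id)."""
    species_ids = [s.species_id for s in species]
    species_of = {p.protein_id: p.species_id for p in proteins}
    rows = {}
    for u in sorted(units, key=lambda u: u.cluster_id):
        counts = dict.fromkeys(species_ids, 0)
        for pid in u.members:
            sp = species_of.get(pid)
            if sp is None or sp not in counts:
                raise DataError(f"protein {pid} has unknown species {sp!r}")
            counts[sp] += 1
        rows[u.cluster_id] = counts
    return pd.DataFrame.from_dict(rows, orient="index", columns=species_ids,
                                  dtype=int)


def _split_columns(species: list[SpeciesInfo]) -> tuple[list[str], list[str]]:
    outgroups = [s.species_id for s in species if s.is_outgroup]
    metazoans = [s.species_id for s in species if not s.is_outgroup]
    if len(outgroups) != 2:
        raise DataError(f"expected exactly 2 outgroup species, found {len(outgroups)}")
    return outgroups, metazoans


def lhca_subset(matrix: pd.DataFrame, species: list[SpeciesInfo]) -> list[str]:
    """Clusters with >=1 protein in either outgroup and >=1 metazoan member."""
    outgroups, metazoans = _split_columns(species)
    has_out = matrix[outgroups].sum(axis=1) >= 1
    has_met = (matrix[metazoans] > 0).any(axis=1)
    return list(matrix.index[has_out & has_met])


@dataclass
class LhcaEstimate:
    cluster_id: str
    c_out1: int
    c_out2: int
    estimate: int  # ceil((c_out1 + c_out2) / 2)


def lhca_proteome(
    matrix: pd.DataFrame,
    subset: list[str],
    species: list[SpeciesInfo],
    include_zero_outgroup: bool = True,
) -> tuple[list[LhcaEstimate], int]:
    """Reconstruct the ancestral proteome size per cluster and in total.

    The per-cluster estimate averages the two outgroup counts and rounds
    up. By default a zero count in the non-possessing outgroup is part
    of the average (so (0, 2) -> 1); setting ``include_zero_outgroup``
    False averages over the nonzero outgroup counts only.
    """
    outgroups, _ = _split_columns(species)
    o1, o2 = outgroups
    estimates = []
    for cid in subset:
        c1, c2 = int(matrix.at[cid, o1]), int(matrix.at[cid, o2])
        if include_zero_outgroup:
            est = math.ceil((c1 + c2) / 2)
        else:
            nonzero = [c for c in (c1, c2) if c > 0]
            est = math.ceil(sum(nonzero) / len(nonzero)) if nonzero else 0
        estimates.append(LhcaEstimate(cid, c1, c2, est))
    return estimates, sum(e.estimate for e in estimates)


@dataclass
class InnovationReport:
    metazoan_innovation: list[str]
    species_specific: list[str]
    lhca: list[str]
    other: list[str]


def innovation_classes(matrix: pd.DataFrame,
                       species: list[SpeciesInfo]) -> InnovationReport:
    """Partition clusters into LHCA / metazoan-innovation / species-specific / other.

    Species-specific takes precedence over metazoan innovation (a
    cluster confined to one metazoan species is species-specific, not a
    metazoan innovation, which requires at least two metazoan species).
    The four classes are disjoint and cover every cluster.
    """
    outgroups, metazoans = _split_columns(species)
    lhca = set(lhca_subset(matrix, species))
    meta_inno, specific, other = [], [], []
    for cid in matrix.index:
        row = matrix.loc[cid]
        if cid in lhca:
            continue
        n_species = int((row > 0).sum())
        no_outgroup = int(row[outgroups].sum()) == 0
        n_meta = int((row[metazoans] > 0).sum())
        if n_species == 1:
            specific.append(cid)
        elif no_outgroup and n_meta >= 2:
            meta_inno.append(cid)
        else:
            other.append(cid)
    return InnovationReport(meta_inno, specific, sorted(lhca), other)


def standardize(matrix: pd.DataFrame,
                rows: list[str] | None = None) -> tuple[pd.DataFrame, list[str]]:
    """Row z-scores: (x - row mean) / row sample sd (ddof=1).

    Zero-variance rows become all-zero and are returned in the flagged
    list. Rows shorter than two entries cannot be standardised.
    """
    sub = matrix.loc[rows] if rows is not None else matrix
    if sub.shape[1] < 2:
        raise DataError("standardize: need at least 2 species columns")
    x = sub.astype(float)
    mean = x.mean(axis=1)
    sd = x.std(axis=1, ddof=1)
    flagged = list(x.index[sd == 0])
    safe_sd = sd.replace(0, 1.0)
    z = x.sub(mean, axis=0).div(safe_sd, axis=0)
    z.loc[flagged] = 0.0
    return z, flagged


@dataclass
class SummaryReport:
    per_species: pd.DataFrame  # total, membrane, percent
    rho_membrane_vs_total: float
    class_shares: dict[str, int] = field(default_factory=dict)
    n_classified: int = 0
    n_total: int = 0
    percent_classified: int = 0


def summary_statistics(
    per_species: pd.DataFrame,
    class_counts: dict[str, int] | None = None,
) -> SummaryReport:
    """Species-table statistics plus functional-class shares.

    ``per_species`` must carry ``total`` and ``membrane`` columns (one
    row per species). ``class_counts`` maps functional class to protein
    count; shares are integer percentages of the classified total
    (classes other than ambiguous/no_description).
    """
    df = per_species.copy()
    df["percent"] = [integer_percent(m, t)
                     for m, t in zip(df["membrane"], df["total"])]
    rho = spearman_rho(df["total"].tolist(), df["membrane"].tolist())
    report = SummaryReport(per_species=df, rho_membrane_vs_total=round(rho, 2))
    if class_counts:
        classified = {k: v for k, v in class_counts.items()
                      if k not in ("ambiguous", "no_description")}
        n_classified = sum(classified.values())
        n_total = sum(class_counts.values())
        report.n_classified = n_classified
        report.n_total = n_total
        report.percent_classified = integer_percent(n_classified, n_total)
        report.class_shares = {k: integer_percent(v, n_classified)
                               for k, v in sorted(classified.items())}
    return report
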