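import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from holomem.comparative import (
    count_matrix,
    innovation_classes,
    lhca_proteome,
    lhca_subset,
    standardize,
    summary_statistics,
)
from holomem.errors import DataError
from holomem.records import Cluster, ProteinRecord, SpeciesInfo
from holomem.stats import spearman_rho

SPECIES = [
    SpeciesInfo("out1", "outgroup"),
    SpeciesInfo("out2", "outgroup"),
    SpeciesInfo("metA", "metazoan-invertebrate"),
    SpeciesInfo("metB", "metazoan-vertebrate", is_human_proxy=True),
]


def matrix(rows: dict) -> pd.DataFrame:
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=[s.species_id for s in SPECIES],
                                  dtype=int)


class TestCountMatrix:
    def test_counts_per_species(self):
        proteins = [ProteinRecord("p1", "g1", "out1", 100),
                    ProteinRecord("p2", "g2", "out1", 100),
                    ProteinRecord("p3", "g3", "metA", 100)]
        units = [Cluster("c1", 2, members=["p1", "p2", "p3"])]
        m = count_matrix(units, proteins, SPECIES)
        assert m.loc["c1"].tolist() == [2, 0, 1, 0]

    def test_empty_cluster_set_gives_empty_matrix(self):
        m = count_matrix([], [], SPECIES)
        assert m.empty and list(m.columns) == [s.species_id for s in SPECIES]

    def test_unknown_species_is_a_data_error(self):
        proteins = [ProteinRecord("p1", "g1", "mars", 100)]
        with pytest.raises(DataError):
            count_matrix([Cluster("c1", 2, members=["p1"])], proteins, SPECIES)


class TestLhcaSubset:
    def test_outgroup_plus_metazoan_included(self):
        m = matrix({"c": {"out1": 1, "out2": 0, "metA": 3, "metB": 0}})
        assert lhca_subset(m, SPECIES) == ["c"]

    def test_outgroup_only_excluded(self):
        m = matrix({"c": {"out1": 2, "out2": 1, "metA": 0, "metB": 0}})
        assert lhca_subset(m, SPECIES) == []

    def test_metazoan_only_excluded(self):
        m = matrix({"c": {"out1": 0, "out2": 0, "metA": 5, "metB": 1}})
        assert lhca_subset(m, SPECIES) == []


class TestLhcaProteome:
    @pytest.mark.parametrize("c1,c2,expected", [
        (3, 4, 4),   # ceil(3.5)
        (1, 1, 1),
        (0, 2, 1),   # zero count included in the average
    ])
    def test_ceiling_average(self, c1, c2, expected):
        m = matrix({"c": {"out1": c1, "out2": c2, "metA": 1, "metB": 0}})
        estimates, total = lhca_proteome(m, ["c"], SPECIES)
        assert estimates[0].estimate == expected == total

    def test_zero_exclusion_switch(self):
        m = matrix({"c": {"out1": 0, "out2": 2, "metA": 1, "metB": 0}})
        _, total = lhca_proteome(m, ["c"], SPECIES,
                                 include_zero_outgroup=False)
        assert total == 2

    def test_total_monotone_in_outgroup_counts(self):
        base = {"c": {"out1": 2, "out2": 3, "metA": 1, "metB": 0}}
        _, t0 = lhca_proteome(matrix(base), ["c"], SPECIES)
        bumped = {"c": {"out1": 3, "out2": 3, "metA": 1, "metB": 0}}
        _, t1 = lhca_proteome(matrix(bumped), ["c"], SPECIES)
        assert t1 >= t0


class TestInnovationClasses:
    def test_rules(self):
        m = matrix({
            "meta": {"out1": 0, "out2": 0, "metA": 4, "metB": 1},
            "specific": {"out1": 0, "out2": 0, "metA": 3, "metB": 0},
            "ancestral": {"out1": 1, "out2": 0, "metA": 5, "metB": 0},
        })
        inno = innovation_classes(m, SPECIES)
        assert inno.metazoan_innovation == ["meta"]
        assert inno.species_specific == ["specific"]
        assert inno.lhca == ["ancestral"]

    @given(st.integers(0, 2**31 - 1))
    def test_partition_is_disjoint_and_covering(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 4, size=(12, len(SPECIES)))
        counts = counts[counts.sum(axis=1) > 0]
        m = pd.DataFrame(counts, columns=[s.species_id for s in SPECIES],
                         index=[f"c{i}" for i in range(len(counts))])
        inno = innovation_classes(m, SPECIES)
        groups = [inno.lhca, inno.metazoan_innovation, inno.species_specific,
                  inno.other]
        combined = [cid for g in groups for cid in g]
        assert sorted(combined) == sorted(m.index)
        assert len(set(combined)) == len(combined)


class TestStandardize:
    def test_two_point_row_z_scores(self):
        m = pd.DataFrame([[2, 4]], index=["r"], columns=["a", "b"])
        z, flagged = standardize(m)
        assert z.loc["r"].tolist() == pytest.approx(
            [-np.sqrt(0.5), np.sqrt(0.5)])
        assert flagged == []

    def test_constant_row_flagged_and_zeroed(self):
        m = pd.DataFrame([[5, 5, 5]], index=["r"], columns=list("abc"))
        z, flagged = standardize(m)
        assert z.loc["r"].tolist() == [0, 0, 0] and flagged == ["r"]

    def test_rows_have_mean_zero_sd_one(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.integers(0, 30, size=(8, 6)),
                         index=[f"r{i}" for i in range(8)],
                         columns=list("abcdef"))
        z, flagged = standardize(m)
        live = z.drop(index=flagged)
        assert np.allclose(live.mean(axis=1), 0, atol=1e-12)
        assert np.allclose(live.std(axis=1, ddof=1), 1, atol=1e-12)

    def test_single_column_refused(self):
        m = pd.DataFrame([[2]], index=["r"], columns=["a"])
        with pytest.raises(DataError):
            standardize(m)


def rank_then_pearson(x, y):
    """Brute-force Spearman oracle: average ranks, then Pearson."""
    def ranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="mergesort")
        r = np.empty(len(v))
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            r[order[i:j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return r
    rx, ry = ranks(x), ranks(y)
    return float(np.corrcoef(rx, ry)[0, 1])


class TestSpearman:
    def test_identical_rankings_give_one(self):
        assert spearman_rho([1, 2, 3, 4], [10, 20, 30, 40]) == pytest.approx(1.0)

    def test_fewer_than_three_observations_refused(self):
        with pytest.raises(DataError):
            spearman_rho([1, 2], [2, 1])

    @given(st.lists(st.integers(0, 8), min_size=4, max_size=30))
    def test_agrees_with_rank_then_pearson_oracle(self, xs):
        rng = np.random.default_rng(len(xs))
        ys = rng.integers(0, 8, size=len(xs)).tolist()
        if len(set(xs)) < 2 or len(set(ys)) < 2:
            return  # correlation undefined for constant vectors
        assert spearman_rho(xs, ys) == pytest.approx(
            rank_then_pearson(xs, ys), abs=1e-12)


class TestSummaryStatistics:
    def test_report_combines_percent_and_rho(self):
        per_species = pd.DataFrame(
            {"total": [100, 200, 300, 150], "membrane": [25, 60, 90, 30]},
            index=["s1", "s2", "s3", "s4"])
        report = summary_statistics(
            per_species,
            {"enzyme": 50, "receptor": 30, "no_description": 20})
        assert report.per_species.loc["s1", "percent"] == 25
        assert report.percent_classified == 80
        assert report.class_shares == {"enzyme": 63, "receptor": 38}
        assert -1 <= report.rho_membrane_vs_total <= 1
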