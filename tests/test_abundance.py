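"""Count tables, normalization, subsampling and RNA-vs-DNA statistics."""

import math

import numpy as np
import pytest

from sedmeta.abundance import (
    CountTable,
    DatasetPair,
    counts_from_mapping,
    cpm,
    expressed_fraction,
    expressed_percent,
    overlap_stats,
    relative_abundance,
    round_half_up,
    subsample_counts,
    taxon_function_crosstab,
    top_functions,
)
from sedmeta.hits import UNASSIGNED, QueryAssignment
from sedmeta.ontology import FunctionOntology


def fn_table(counts, dataset_id="d"):
    return CountTable.from_counts(counts, dataset_id=dataset_id, unit="function")


class TestCountsFromMapping:
    def test_empty(self):
        t = counts_from_mapping([])
        assert t.counts == {} and t.total_annotated == 0

    def test_basic_tally(self):
        reads = [(f"r{i}", "orf1") for i in range(4)] + [("r9", "orf2")]
        t = counts_from_mapping(reads)
        assert t.counts == {"orf1": 4, "orf2": 1}
        assert t.total_annotated == 5

    def test_unannotated_excluded_from_total(self):
        annotations = {"orf1": ("t", frozenset())}
        t = counts_from_mapping([("r1", "orf1"), ("r2", "ghost")], annotations)
        assert t.total_annotated == 1
        assert t.unannotated == 1

    def test_duplicate_read_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            counts_from_mapping([("r1", "a"), ("r1", "b")])


class TestNormalization:
    def test_single_key_is_100(self):
        assert relative_abundance(fn_table({"a": 7})) == {"a": 100.0}

    def test_percent_values(self):
        ra = relative_abundance(fn_table({"a": 1, "b": 1, "c": 2}))
        assert ra == {"a": 25.0, "b": 25.0, "c": 50.0}

    def test_sums_to_100_and_1e6(self):
        rng = np.random.default_rng(3)
        counts = {f"k{i}": int(c) for i, c in enumerate(rng.integers(1, 1000, size=300))}
        t = fn_table(counts)
        assert math.isclose(sum(relative_abundance(t).values()), 100.0, rel_tol=1e-9)
        assert math.isclose(sum(cpm(t).values()), 1e6, rel_tol=1e-9)

    def test_cpm_unit(self):
        t = fn_table({"a": 463, "rest": 999537})
        assert math.isclose(cpm(t)["a"], 463.0, rel_tol=1e-12)

    def test_zero_total_errors(self):
        with pytest.raises(ValueError):
            relative_abundance(fn_table({}))
        with pytest.raises(ValueError):
            cpm(fn_table({}))


class TestSubsampling:
    def test_full_depth_is_identity(self):
        t = fn_table({"a": 5, "b": 3})
        assert subsample_counts(t, 8, seed=1).counts == {"a": 5, "b": 3}

    def test_zero_depth(self):
        out = subsample_counts(fn_table({"a": 5, "b": 3}), 0, seed=1)
        assert sum(out.counts.values()) == 0

    def test_depth_exceeding_total_errors(self):
        with pytest.raises(ValueError):
            subsample_counts(fn_table({"a": 5}), 6, seed=1)

    def test_exact_depth_and_bounded_by_original(self):
        t = fn_table({f"k{i}": 10 + i for i in range(20)})
        out = subsample_counts(t, 100, seed=11)
        assert sum(out.counts.values()) == 100
        assert all(out.counts[k] <= t.counts[k] for k in t.counts)

    def test_determinism(self):
        t = fn_table({f"k{i}": 50 for i in range(10)})
        a = subsample_counts(t, 123, seed=9).counts
        b = subsample_counts(t, 123, seed=9).counts
        assert a == b

    def test_hypergeometric_expectation(self):
        """Mean subsampled count over many seeds within 3 SE of the
        hypergeometric expectation."""
        t = fn_table({"a": 500, "b": 500})
        n, depth = 1000, 100
        draws = np.array([subsample_counts(t, depth, seed=s).counts.get("a", 0)
                          for s in range(n)])
        # E[a] = 50; Var = depth * p * (1-p) * (N-depth)/(N-1)
        var = depth * 0.25 * (1000 - depth) / 999
        se = math.sqrt(var / n)
        assert abs(draws.mean() - 50.0) < 3 * se


class TestExpressedFraction:
    def test_rounding_matches_worked_ratios(self):
        assert expressed_percent(253, 438) == 58
        assert expressed_percent(34, 64) == 53
        assert expressed_percent(6, 13) == 46
        assert expressed_percent(7, 12) == 58

    def test_round_half_up(self):
        assert round_half_up(0.5) == 1
        assert round_half_up(57.5) == 58
        assert round_half_up(57.49) == 57

    def make_pair_and_onto(self):
        onto = FunctionOntology()
        for i in range(10):
            onto.add(f"F{i}", "", [("cat", "m", "s")])
        dna = fn_table({f"F{i}": 2 for i in range(10)}, "dna")
        rna = fn_table({"F0": 1, "F1": 4, "F2": 1}, "rna")
        return DatasetPair(rna=rna, dna=dna), onto

    def test_per_category_counts(self):
        pair, onto = self.make_pair_and_onto()
        df = expressed_fraction(pair, onto, level=1)
        row = df[df.category == "cat"].iloc[0]
        assert (row.n_expressed, row.n_total, row.percent) == (3, 10, 30)

    def test_zero_expressed_is_zero_percent(self):
        onto = FunctionOntology()
        onto.add("F0", "", [("cat", "m", "s")])
        pair = DatasetPair(rna=fn_table({}, "rna"), dna=fn_table({"F0": 1}, "dna"))
        df = expressed_fraction(pair, onto, level=1)
        assert df.iloc[0].percent == 0

    def test_empty_dna_category_is_undefined(self):
        onto = FunctionOntology()
        onto.add("F0", "", [("catA", "m", "s")])
        onto.add("F1", "", [("catB", "m", "s")])
        # catB detected only in RNA -> undefined, not 0
        pair = DatasetPair(rna=fn_table({"F1": 1}, "rna"), dna=fn_table({"F0": 1}, "dna"))
        df = expressed_fraction(pair, onto, level=1).set_index("category")
        assert math.isnan(df.loc["catB", "percent"])
        assert df.loc["catA", "percent"] == 0

    def test_rna_only_functions_not_in_numerator(self):
        onto = FunctionOntology()
        for i in range(4):
            onto.add(f"F{i}", "", [("cat", "m", "s")])
        pair = DatasetPair(rna=fn_table({"F0": 1, "F3": 9}, "rna"),
                           dna=fn_table({"F0": 1, "F1": 1, "F2": 1}, "dna"))
        df = expressed_fraction(pair, onto, level=1)
        row = df.iloc[0]
        assert (row.n_expressed, row.n_total) == (1, 3)

    def test_unit_mismatch_rejected(self):
        with pytest.raises(ValueError):
            DatasetPair(rna=fn_table({}), dna=CountTable("d", "orf"))


class TestOverlap:
    def test_identical_sets(self):
        t = fn_table({"a": 1, "b": 2})
        assert overlap_stats(DatasetPair(rna=t, dna=t)) == (100.0, 100.0)

    def test_headline_shape(self):
        dna = fn_table({f"F{i}": 1 for i in range(10)}, "dna")
        rna = fn_table({"F0": 1, "F1": 1, "F2": 1, "X": 1}, "rna")
        expressed, confirmed = overlap_stats(DatasetPair(rna=rna, dna=dna))
        assert expressed == 30.0
        assert confirmed == 75.0

    def test_disjoint_sets(self):
        pair = DatasetPair(rna=fn_table({"a": 1}), dna=fn_table({"b": 1}))
        assert overlap_stats(pair) == (0.0, 0.0)

    def test_empty_sets_undefined(self):
        pair = DatasetPair(rna=fn_table({}), dna=fn_table({"b": 1}))
        expressed, confirmed = overlap_stats(pair)
        assert expressed == 0.0 and confirmed is None


class TestTopFunctions:
    def test_descending(self):
        assert top_functions(fn_table({"a": 5, "b": 9}), 1) == [("b", 9)]

    def test_lexicographic_ties(self):
        assert top_functions(fn_table({"c": 5, "a": 5}), 2) == [("a", 5), ("c", 5)]

    def test_n_larger_than_table(self):
        assert len(top_functions(fn_table({"a": 1, "b": 2}), 10)) == 2


class TestCrosstab:
    def make_onto(self):
        onto = FunctionOntology()
        onto.add("F1", "", [("P1", "m", "s")])
        onto.add("F2", "", [("P2", "m", "s")])
        return onto

    def test_single_cell(self):
        onto = self.make_onto()
        a = [QueryAssignment("q1", "T", frozenset({"F1"}), 1)]
        df, unassigned = taxon_function_crosstab(a, {"q1": 10}, onto, level=1)
        assert df.loc["T", "P1"] == 10
        assert unassigned == 0

    def test_column_sum_conservation(self):
        onto = self.make_onto()
        a = [
            QueryAssignment("q1", "T1", frozenset({"F1"}), 1),
            QueryAssignment("q2", "T2", frozenset({"F1"}), 1),
            QueryAssignment("q3", "T2", frozenset({"F2"}), 1),
        ]
        df, _ = taxon_function_crosstab(a, {"q1": 3, "q2": 4, "q3": 5}, onto, level=1)
        assert df.to_numpy().sum() == 12
        assert df["P1"].sum() == 7

    def test_unassigned_excluded_and_reported(self):
        onto = self.make_onto()
        a = [
            QueryAssignment("q1", "T1", frozenset({"F1"}), 1),
            QueryAssignment("q2", UNASSIGNED, frozenset(), 0),
        ]
        df, unassigned = taxon_function_crosstab(a, {"q1": 2, "q2": 9}, onto, level=1)
        assert UNASSIGNED not in df.index
        assert unassigned == 9
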