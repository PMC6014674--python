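from __future__ import annotations

import datetime as dt
import math
import random

import pytest
from hypothesis import given, settings, strategies as st

from odm_insight import fixtures
from odm_insight.model import CodeListDef, DataType, ItemDef, Oid
from odm_insight.reader import parse_odm
from odm_insight.stats import (
    DEFAULT_BINS,
    UnsupportedDataTypeError,
    analyze,
    categorize,
    count_references,
    flag_repeat_keys,
    make_histogram,
    stats_dichotomous,
    stats_interval,
    stats_nominal,
    stats_ordinal,
    stats_ratio,
)
from odm_insight.validation import validate_dataset

import oracles


def _item(dtype, codelist=None):
    return ItemDef(Oid("I"), "i", DataType(dtype), codelist=codelist)


class TestCategorize:
    @pytest.mark.parametrize("dtype,expected", [
        ("boolean", "dichotomous"),
        ("string", "nominal"), ("text", "nominal"),
        ("integer", "ratio"), ("float", "ratio"), ("double", "ratio"),
        ("date", "interval"), ("time", "interval"), ("datetime", "interval"),
    ])
    def test_base_type_mapping(self, dtype, expected):
        assert categorize(_item(dtype)) == expected

    def test_codelist_wins_over_base_type(self):
        cl = CodeListDef(Oid("C"), "c", DataType("integer"),
                         options=(("1", "a"), ("2", "b")))
        assert categorize(_item("integer", cl)) == "ordinal"

    def test_unsupported_type_signals(self):
        with pytest.raises(UnsupportedDataTypeError):
            categorize(_item("partialDate"))


class TestDichotomous:
    def test_55_45(self):
        summary, chart = stats_dichotomous([True] * 55 + [False] * 45)
        assert (summary.true_count, summary.false_count) == (55, 45)
        assert chart.kind == "pie" and chart.counts == (55, 45)

    def test_all_true(self):
        summary, _ = stats_dichotomous([True, True, True])
        assert (summary.true_count, summary.false_count) == (3, 0)

    def test_empty_has_no_chart(self):
        summary, chart = stats_dichotomous([])
        assert (summary.true_count, summary.false_count) == (0, 0)
        assert chart is None

    @given(st.lists(st.booleans(), max_size=200))
    def test_matches_brute_force_tally(self, values):
        summary, chart = stats_dichotomous(values)
        assert (summary.true_count, summary.false_count) == oracles.bool_counts(values)
        if chart:
            assert sum(chart.counts) == len(values)


class TestNominal:
    def test_top3_example(self):
        top = stats_nominal(["a", "b", "a", "c", "a", "b"])
        assert top.entries == (("a", 3), ("b", 2), ("c", 1))
        assert top.diversity == 3

    def test_single_value(self):
        top = stats_nominal(["x"])
        assert top.entries == (("x", 1),) and top.diversity == 1

    def test_case_sensitive_exact_match(self):
        top = stats_nominal(["A", "a"])
        assert top.diversity == 2

    @given(st.lists(st.text(alphabet="abcde", max_size=2), min_size=1, max_size=80))
    def test_matches_oracle_and_order_invariant(self, values):
        top = stats_nominal(values)
        assert list(top.entries) == oracles.top_entries(values)
        assert top.diversity == oracles.distinct_count(values)
        shuffled = list(values)
        random.Random(0).shuffle(shuffled)
        assert stats_nominal(shuffled) == top

    @given(st.lists(st.text(alphabet="abcdefgh", max_size=3), max_size=80))
    def test_top_list_invariants(self, values):
        top = stats_nominal(values)
        counts = [c for _, c in top.entries]
        assert counts == sorted(counts, reverse=True)
        assert len(top.entries) == min(3, top.diversity)
        assert all(c >= 1 for c in counts)


def _cl(n):
    return CodeListDef(Oid("CL"), "cl", DataType("string"),
                       options=tuple((f"O{i:02d}", f"opt {i}") for i in range(1, n + 1)))


class TestOrdinal:
    def test_three_options_all_shown(self):
        cl = CodeListDef(Oid("CL"), "cl", DataType("string"),
                         options=(("Yes", "y"), ("No", "n"), ("Maybe", "m")))
        values = ["Yes"] * 8 + ["No"] * 4 + ["Maybe"] * 3
        top, chart = stats_ordinal(values, cl)
        assert top.entries == (("Yes", 8), ("No", 4), ("Maybe", 3))
        assert top.diversity == 3 and top.diversity_total == 3
        assert chart.kind == "bar"
        assert chart.labels == ("Yes", "No", "Maybe")
        assert sum(chart.counts) == len(values)

    def test_fifteen_options_top_nine_plus_others(self):
        cl = _cl(15)
        values = []
        for i in range(1, 16):
            values.extend([f"O{i:02d}"] * (16 - i))
        top, chart = stats_ordinal(values, cl)
        assert len(chart.labels) == 10
        assert chart.labels[-1] == "others"
        assert chart.counts[-1] == len(values) - sum(chart.counts[:9])
        assert sum(chart.counts) == len(values)

    def test_ten_options_no_others(self):
        cl = _cl(10)
        values = [f"O{i:02d}" for i in range(1, 11)]
        _, chart = stats_ordinal(values, cl)
        assert len(chart.labels) == 10 and "others" not in chart.labels

    def test_unobserved_options_get_zero_bars(self):
        cl = _cl(4)
        _, chart = stats_ordinal(["O01", "O01"], cl)
        assert chart.counts == (2, 0, 0, 0)

    def test_diversity_counts_observed_over_total(self):
        cl = _cl(5)
        top, _ = stats_ordinal(["O01", "O02"], cl)
        assert (top.diversity, top.diversity_total) == (2, 5)


class TestInterval:
    def test_two_datetimes_range(self):
        lo = dt.datetime(1920, 5, 5, 13, 54, 47)
        hi = dt.datetime(2010, 6, 9, 20, 11, 59)
        summary, chart = stats_interval([hi, lo])
        assert summary.minimum == lo and summary.maximum == hi
        assert chart.kind == "histogram"

    def test_single_date(self):
        d = dt.date(2000, 1, 1)
        summary, chart = stats_interval([d])
        assert summary.minimum == summary.maximum == d
        assert chart.counts == (1,)

    def test_no_data(self):
        assert stats_interval([]) == (None, None)

    def test_hundred_dates_match_binning_oracle(self):
        rng = random.Random(42)
        dates = [dt.date(1970, 1, 1) + dt.timedelta(days=rng.randint(0, 5000))
                 for _ in range(100)]
        _, chart = stats_interval(dates, n_bins=DEFAULT_BINS)
        encoded = [(d - dt.date(1970, 1, 1)).days for d in dates]
        assert list(chart.counts) == oracles.histogram_counts(encoded, DEFAULT_BINS)


class TestRatio:
    def test_single_value_conventions(self):
        summary, chart = stats_ratio([5.0])
        assert summary.minimum == summary.maximum == summary.mean == 5.0
        assert summary.median == 5.0 and summary.stddev == 0.0
        assert chart.counts == (1,)

    def test_known_sample(self):
        # direct formula recomputation: mean 40/8, median (4+5)/2, squared
        # deviations 9+1+1+1+0+0+4+16 = 32, sample variance 32/7
        summary, _ = stats_ratio([2, 4, 4, 4, 5, 5, 7, 9])
        assert summary.mean == 5.0
        assert summary.median == 4.5
        assert (summary.minimum, summary.maximum) == (2.0, 9.0)
        assert summary.stddev == pytest.approx(math.sqrt(32 / 7), abs=1e-12)

    def test_no_data(self):
        assert stats_ratio([]) == (None, None)

    @given(st.lists(st.floats(min_value=-1e6, max_value=1e6), min_size=1,
                    max_size=100))
    @settings(max_examples=60)
    def test_matches_direct_formulas(self, values):
        summary, chart = stats_ratio(values)
        expected = oracles.ratio_summary([float(v) for v in values])
        assert summary.mean == pytest.approx(expected["mean"], rel=1e-9, abs=1e-9)
        assert summary.median == pytest.approx(expected["median"], rel=1e-9, abs=1e-9)
        assert summary.stddev == pytest.approx(expected["stddev"], rel=1e-6, abs=1e-9)
        assert summary.minimum == expected["min"]
        assert summary.maximum == expected["max"]
        assert sum(chart.counts) == len(values)


class TestMakeHistogram:
    def test_uniform_partition(self):
        chart = make_histogram(list(range(10)), 10)
        assert chart.counts == (1,) * 10
        assert chart.borders[0] == 0.0 and chart.borders[-1] == 9.0

    def test_degenerate_range_single_bin(self):
        chart = make_histogram([3.3] * 7, 10)
        assert chart.counts == (7,)
        assert chart.borders[0] < 3.3 < chart.borders[1]

    def test_thousand_uniform_values_match_oracle(self):
        rng = random.Random(7)
        values = [rng.uniform(0, 100) for _ in range(1000)]
        chart = make_histogram(values, 10)
        assert list(chart.counts) == oracles.histogram_counts(values, 10)

    @given(st.lists(st.floats(min_value=-1e4, max_value=1e4), min_size=1,
                    max_size=120),
           st.integers(min_value=1, max_value=20))
    @settings(max_examples=60)
    def test_conservation_and_monotone_borders(self, values, bins):
        chart = make_histogram(values, bins)
        assert sum(chart.counts) == len(values)
        assert all(a < b for a, b in zip(chart.borders, chart.borders[1:]))


class TestCountsAndFlags:
    def _clean(self, spec):
        xml, manifest = fixtures.generate(spec)
        parsed = parse_odm(xml)
        clean, invalid = validate_dataset(parsed.metadata, parsed.clinical)
        return parsed.metadata, clean, invalid, manifest

    def test_repeat_inflates_references_not_subjects(self):
        tree, clean, _, manifest = self._clean(
            fixtures.FixtureSpec(seed=21, subjects=1, repeat_prob=1.0,
                                 max_repeats=3)
        )
        for el in tree.elements():
            cs = count_references(el, clean)
            facts = manifest.elements[el.path]
            assert (cs.reference_count, cs.subject_count) == (
                facts["reference_count"], facts["subject_count"])
            assert cs.subject_count <= 1

    def test_never_referenced_element_is_zero(self):
        tree, clean, _, _ = self._clean(fixtures.FixtureSpec(seed=22, subjects=0))
        for el in tree.elements():
            assert count_references(el, clean) .reference_count == 0

    def test_flag_repeat_keys_matches_manifest(self):
        tree, clean, _, manifest = self._clean(
            fixtures.FixtureSpec(seed=23, subjects=5, repeat_prob=0.5)
        )
        for el in tree.elements():
            assert flag_repeat_keys(el, clean) == manifest.elements[el.path]["repeat_flag"]

    def test_no_repeats_means_equality(self):
        tree, clean, _, _ = self._clean(
            fixtures.FixtureSpec(seed=24, subjects=5, repeat_prob=0.0)
        )
        for el in tree.elements():
            cs = count_references(el, clean)
            assert cs.subject_count == cs.reference_count


class TestPositionalDistinctness:
    def test_shared_form_statistics_are_independent(self):
        spec = fixtures.FixtureSpec(seed=30, subjects=5, events=2,
                                    reuse_form_across_events=True,
                                    missing_rate=0.2)
        xml, manifest = fixtures.generate(spec)
        parsed = parse_odm(xml)
        clean, invalid = validate_dataset(parsed.metadata, parsed.clinical)
        outcome = analyze(parsed.metadata, clean, invalid)
        item_paths = [p for p in manifest.items if manifest.items[p]["category"]]
        assert any(p[0] == "SE1" for p in item_paths)
        assert any(p[0] == "SE2" for p in item_paths)
        for path in item_paths:
            raws = sorted(oracles.item_raw_values(clean, path))
            assert raws == manifest.items[path]["values"]
        # merging the two placements' multisets reproduces single-placement
        # statistics over the union data
        for p1 in item_paths:
            if p1[0] != "SE1":
                continue
            p2 = ("SE2",) + p1[1:]
            if p2 not in item_paths:
                continue
            union = sorted(oracles.item_raw_values(clean, p1)
                           + oracles.item_raw_values(clean, p2))
            merged = sorted(manifest.items[p1]["values"]
                            + manifest.items[p2]["values"])
            assert union == merged


class TestAnalyze:
    def test_zero_valid_values_still_reported(self):
        spec = fixtures.FixtureSpec(seed=31, subjects=3, missing_rate=1.0)
        xml, _ = fixtures.generate(spec)
        parsed = parse_odm(xml)
        clean, invalid = validate_dataset(parsed.metadata, parsed.clinical)
        outcome = analyze(parsed.metadata, clean, invalid)
        assert outcome.items  # items appear even with no data
        for stat in outcome.items:
            assert stat.summary is None

    def test_unsupported_items_are_skipped_and_listed(self):
        spec = fixtures.FixtureSpec(seed=32, subjects=3,
                                    invalid_plan=(("UNSUPPORTED_TYPE", 1),))
        xml, _ = fixtures.generate(spec)
        parsed = parse_odm(xml)
        clean, invalid = validate_dataset(parsed.metadata, parsed.clinical)
        outcome = analyze(parsed.metadata, clean, invalid)
        assert any(dtype == "partialDate" for _, dtype in outcome.skipped_items)
        assert all(s.element.oid != "I_PARTIAL" for s in outcome.items)

    def test_invalid_value_warning_propagates(self):
        spec = fixtures.FixtureSpec(seed=33, subjects=4,
                                    invalid_plan=(("TYPE_MISMATCH", 1),))
        xml, _ = fixtures.generate(spec)
        parsed = parse_odm(xml)
        clean, invalid = validate_dataset(parsed.metadata, parsed.clinical)
        outcome = analyze(parsed.metadata, clean, invalid)
        flagged_items = [s for s in outcome.items if s.invalid_value_warning]
        assert len(flagged_items) == 1
        item_path = flagged_items[0].element.path
        for depth in range(1, 4):
            assert outcome.invalid_flags[item_path[:depth]]
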