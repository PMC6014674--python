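from __future__ import annotations

import csv
import datetime as dt
import io

import pytest
from hypothesis import given, strategies as st

from odm_insight import fixtures
from odm_insight.model import CodeListDef, DataType, ItemDef, Oid
from odm_insight.reader import parse_odm
from odm_insight.validation import (
    NOT_IN_CODELIST,
    TYPE_MISMATCH,
    UNDEFINED_REFERENCE,
    UNSUPPORTED_TYPE,
    InvalidReason,
    TypedValue,
    export_invalid_csv,
    validate_dataset,
    validate_value,
)

import oracles


def _item(dtype, codelist=None):
    return ItemDef(Oid("I1"), "item", DataType(dtype), codelist=codelist)


CL = CodeListDef(Oid("CL"), "cl", DataType("string"),
                 options=(("1", "one"), ("2", "two"), ("3", "three")))


class TestValidateValue:
    @pytest.mark.parametrize("raw,expected", [
        ("true", True), ("false", False), ("1", True), ("0", False),
    ])
    def test_boolean_lexical_space(self, raw, expected):
        result = validate_value(_item("boolean"), raw)
        assert isinstance(result, TypedValue)
        assert result.payload is expected

    @pytest.mark.parametrize("raw", ["True", "FALSE", "yes", "01", " 1", "1 "])
    def test_boolean_rejects_other_tokens(self, raw):
        result = validate_value(_item("boolean"), raw)
        assert isinstance(result, InvalidReason) and result.code == TYPE_MISMATCH

    def test_integer_rejects_decimal(self):
        result = validate_value(_item("integer"), "4.2")
        assert isinstance(result, InvalidReason) and result.code == TYPE_MISMATCH

    @pytest.mark.parametrize("raw", ["7", "-12", "+3"])
    def test_integer_accepts_signed_digits(self, raw):
        result = validate_value(_item("integer"), raw)
        assert isinstance(result, TypedValue) and result.kind == "number"

    def test_no_whitespace_trimming(self):
        assert isinstance(validate_value(_item("integer"), " 5"), InvalidReason)
        assert isinstance(validate_value(_item("float"), "5 "), InvalidReason)

    @pytest.mark.parametrize("dtype,raw,ok", [
        ("float", "3.25", True), ("double", "-1e3", True), ("float", "x", False),
        ("date", "2020-02-29", True), ("date", "2020-02-30", False),
        ("date", "20200229", False),
        ("time", "13:54:47", True), ("time", "25:00:00", False),
        ("datetime", "2020-01-02T03:04:05", True),
        ("datetime", "2020-01-02 03:04:05", False),
        ("datetime", "2020-01-02T03:04:05Z", True),
    ])
    def test_conversion_matrix(self, dtype, raw, ok):
        result = validate_value(_item(dtype), raw)
        assert isinstance(result, TypedValue) is ok

    def test_datetime_zone_normalized_to_instant(self):
        a = validate_value(_item("datetime"), "2020-01-01T12:00:00+02:00")
        b = validate_value(_item("datetime"), "2020-01-01T10:00:00Z")
        assert a.payload == b.payload == dt.datetime(2020, 1, 1, 10, 0, 0)

    def test_codelist_membership(self):
        ok = validate_value(_item("string", CL), "2")
        assert isinstance(ok, TypedValue) and ok.kind == "code"
        bad = validate_value(_item("string", CL), "5")
        assert isinstance(bad, InvalidReason) and bad.code == NOT_IN_CODELIST

    def test_codelist_conversion_failure_reported_first(self):
        int_cl = CodeListDef(Oid("C"), "c", DataType("integer"),
                             options=(("1", "one"), ("2", "two")))
        bad = validate_value(_item("integer", int_cl), "abc")
        assert isinstance(bad, InvalidReason) and bad.code == TYPE_MISMATCH

    def test_unsupported_type(self):
        result = validate_value(_item("partialDate"), "2020-01")
        assert isinstance(result, InvalidReason) and result.code == UNSUPPORTED_TYPE

    @given(st.text(max_size=20))
    def test_pure_function(self, raw):
        item = _item("integer")
        assert validate_value(item, raw) == validate_value(item, raw)

    @given(st.text(max_size=6))
    def test_boolean_accepts_exactly_four_tokens(self, raw):
        result = validate_value(_item("boolean"), raw)
        assert isinstance(result, TypedValue) == (raw in {"true", "false", "1", "0"})


def _pipeline(spec):
    xml, manifest = fixtures.generate(spec)
    parsed = parse_odm(xml)
    assert parsed.ok
    clean, invalid = validate_dataset(parsed.metadata, parsed.clinical)
    return parsed, clean, invalid, manifest


class TestValidateDataset:
    def test_error_free_dataset_is_identity(self):
        parsed, clean, invalid, _ = _pipeline(
            fixtures.FixtureSpec(seed=11, subjects=4)
        )
        assert invalid == []
        assert oracles.path_instances(clean) == oracles.path_instances(parsed.clinical)

    def test_injected_errors_recovered_exactly(self):
        plan = (("TYPE_MISMATCH", 4), ("NOT_IN_CODELIST", 2),
                ("UNDEFINED_REFERENCE", 3), ("UNSUPPORTED_TYPE", 2))
        _, _, invalid, manifest = _pipeline(
            fixtures.FixtureSpec(
                seed=12, subjects=6, items_per_group=4, invalid_plan=plan,
                type_weights={"codelist": 1.0, "integer": 1.0, "date": 1.0},
            )
        )
        got = {}
        for rec in invalid:
            got[rec.reason.code] = got.get(rec.reason.code, 0) + 1
        assert got == manifest.injected_counts()
        for rec in invalid:
            assert rec.reason.code in (
                UNDEFINED_REFERENCE, TYPE_MISMATCH, NOT_IN_CODELIST, UNSUPPORTED_TYPE
            )

    def test_undefined_reference_excludes_value(self):
        _, clean, invalid, _ = _pipeline(
            fixtures.FixtureSpec(seed=13, subjects=3,
                                 invalid_plan=(("UNDEFINED_REFERENCE", 2),))
        )
        undefined = [r for r in invalid if r.reason.code == UNDEFINED_REFERENCE]
        assert len(undefined) == 2
        for path in oracles.path_instances(clean):
            assert "UNDEF_ITEM" not in path

    @pytest.mark.parametrize("seed", range(6))
    def test_conservation_of_present_values(self, seed, run_pipeline):
        spec = fixtures.FixtureSpec(
            seed=seed, subjects=4, items_per_group=4, missing_rate=0.3,
            invalid_plan=(("TYPE_MISMATCH", 2),),
        )
        xml, _ = fixtures.generate(spec)
        parsed = parse_odm(xml)
        clean, invalid = validate_dataset(parsed.metadata, parsed.clinical)
        original = sum(
            len(oracles.item_raw_values(parsed.clinical, path))
            for path in oracles.path_instances(parsed.clinical)
            if len(path) == 4
        )
        kept = sum(
            len(oracles.item_raw_values(clean, path))
            for path in oracles.path_instances(clean)
            if len(path) == 4
        )
        assert original == kept + len(invalid)

    def test_validation_is_idempotent(self):
        parsed, clean, _, _ = _pipeline(
            fixtures.FixtureSpec(seed=14, subjects=4,
                                 invalid_plan=(("NOT_IN_CODELIST", 1),))
        )
        clean2, invalid2 = validate_dataset(parsed.metadata, clean)
        assert invalid2 == []
        assert oracles.path_instances(clean2) == oracles.path_instances(clean)


class TestExportInvalidCsv:
    def _records(self):
        _, _, invalid, _ = _pipeline(
            fixtures.FixtureSpec(seed=15, subjects=5, items_per_group=4,
                                 invalid_plan=(("TYPE_MISMATCH", 3),))
        )
        return invalid

    def test_empty_list_header_only(self):
        sink = io.StringIO()
        assert export_invalid_csv([], sink) == 0
        rows = list(csv.reader(io.StringIO(sink.getvalue())))
        assert len(rows) == 1 and rows[0][0] == "subject_key"

    def test_round_trip(self):
        records = self._records()
        sink = io.StringIO()
        assert export_invalid_csv(records, sink) == len(records) == 3
        rows = list(csv.reader(io.StringIO(sink.getvalue())))
        assert len(rows) == len(records) + 1
        for rec, row in zip(records, rows[1:]):
            assert row[0] == rec.subject_key
            assert row[7] == rec.path[-1]
            assert row[9] == rec.reason.code

    def test_comma_in_value_is_quoted(self):
        rec = self._records()[0]
        from dataclasses import replace

        rec = replace(rec, raw_value='a,"b"')
        sink = io.StringIO()
        export_invalid_csv([rec], sink)
        rows = list(csv.reader(io.StringIO(sink.getvalue())))
        assert rows[1][8] == 'a,"b"'
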