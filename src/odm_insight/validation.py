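"""Second-stage semantic validation of clinical data.

Structural validation guarantees the document's shape; this stage checks
its *content*: every clinical path must resolve into the positional
metadata tree, every item value must convert into its declared data type,
and codelist-backed values must be members of their list.  Findings never
abort the run — each one becomes an :class:`InvalidValueRecord` and the
offending entry is excluded from further analyses.
"""

from __future__ import annotations

import csv
import datetime as _dt
import re
from dataclasses import dataclass, replace
from typing import List, Optional, Tuple, Union

from .model import (
    ClinicalDataset,
    ElementInstance,
    ItemDef,
    MetadataTree,
    PathT,
    RepeatKeysT,
    SubjectRecord,
    resolve_instance_path,
)

UNDEFINED_REFERENCE = "UNDEFINED_REFERENCE"
TYPE_MISMATCH = "TYPE_MISMATCH"
NOT_IN_CODELIST = "NOT_IN_CODELIST"
UNSUPPORTED_TYPE = "UNSUPPORTED_TYPE"

REASON_CODES = (UNDEFINED_REFERENCE, TYPE_MISMATCH, NOT_IN_CODELIST, UNSUPPORTED_TYPE)


@dataclass(frozen=True)
class InvalidReason:
    code: str
    detail: str = ""


@dataclass(frozen=True)
class InvalidValueRecord:
    """One detected semantic error, locatable down to the repeat key."""

    subject_key: str
    path: PathT
    repeat_keys: RepeatKeysT
    raw_value: Optional[str]
    reason: InvalidReason


@dataclass(frozen=True)
class TypedValue:
    """A successfully converted clinical value.

    ``kind`` is one of ``boolean``, ``number``, ``text``, ``timepoint``,
    ``code``; numbers are held at double precision.
    """

    kind: str
    payload: object
    path: PathT = ()


_INT_RE = re.compile(r"[+-]?\d+\Z")
_FLOAT_RE = re.compile(r"[+-]?(\d+(\.\d*)?|\.\d+)([eE][+-]?\d+)?\Z")
_DATE_RE = re.compile(r"\d{4}-\d{2}-\d{2}\Z")
_TIME_RE = re.compile(r"\d{2}:\d{2}:\d{2}(\.\d+)?(Z|[+-]\d{2}:\d{2})?\Z")
_DATETIME_RE = re.compile(
    r"\d{4}-\d{2}-\d{2}T\d{2}:\d{2}:\d{2}(\.\d+)?(Z|[+-]\d{2}:\d{2})?\Z"
)

_BOOL_TOKENS = {"true": True, "false": False, "1": True, "0": False}


def _parse_timepoint(name: str, raw: str) -> object:
    """Parse an ISO 8601 lexical form into a comparable instant.

    Zone-aware datetimes/times are normalized to UTC and returned naive so
    the whole value set is totally ordered.
    """
    iso = raw.replace("Z", "+00:00")
    if name == "date":
        if not _DATE_RE.match(raw):
            raise ValueError(raw)
        return _dt.date.fromisoformat(raw)
    if name == "time":
        if not _TIME_RE.match(raw):
            raise ValueError(raw)
        t = _dt.time.fromisoformat(iso)
        if t.tzinfo is not None:
            anchor = _dt.datetime.combine(_dt.date(2000, 1, 1), t)
            t = anchor.astimezone(_dt.timezone.utc).time()
        return t
    if not _DATETIME_RE.match(raw):
        raise ValueError(raw)
    dt = _dt.datetime.fromisoformat(iso)
    if dt.tzinfo is not None:
        dt = dt.astimezone(_dt.timezone.utc).replace(tzinfo=None)
    return dt


def validate_value(item: ItemDef, raw: str) -> Union[TypedValue, InvalidReason]:
    """Convert one raw value string against an item definition.

    Pure function; returns a :class:`TypedValue` on success and an
    :class:`InvalidReason` on failure (never raises).  Conversion happens
    first, codelist membership second, and the first failure is reported.
    Boolean accepts exactly the lowercase tokens true/false/1/0; values are
    not whitespace-trimmed before conversion.
    """
    name = item.data_type.name
    if not item.data_type.supported:
        return InvalidReason(UNSUPPORTED_TYPE, f"data type {name!r} is not implemented")
    if name == "boolean":
        if raw in _BOOL_TOKENS:
            typed = TypedValue("boolean", _BOOL_TOKENS[raw])
        else:
            return InvalidReason(TYPE_MISMATCH, f"{raw!r} is not a boolean literal")
    elif name == "integer":
        if _INT_RE.match(raw):
            typed = TypedValue("number", float(int(raw)))
        else:
            return InvalidReason(TYPE_MISMATCH, f"{raw!r} is not an integer")
    elif name in ("float", "double"):
        if _FLOAT_RE.match(raw):
            typed = TypedValue("number", float(raw))
        else:
            return InvalidReason(TYPE_MISMATCH, f"{raw!r} is not a {name}")
    elif name in ("date", "time", "datetime"):
        try:
            typed = TypedValue("timepoint", _parse_timepoint(name, raw))
        except ValueError:
            return InvalidReason(TYPE_MISMATCH, f"{raw!r} is not an ISO 8601 {name}")
    else:  # string / text
        typed = TypedValue("text", raw)
    if item.codelist is not None:
        if raw not in item.codelist.codes:
            return InvalidReason(
                NOT_IN_CODELIST,
                f"{raw!r} not among the {len(item.codelist.codes)} coded values "
                f"of list {item.codelist.oid}",
            )
        return TypedValue("code", raw)
    return typed


def _validate_instance(
    tree: MetadataTree,
    subject_key: str,
    instance: ElementInstance,
    invalid: List[InvalidValueRecord],
) -> Optional[ElementInstance]:
    element = resolve_instance_path(tree, instance)
    if element is None:
        # one record for the unresolved level; the whole subtree is dropped
        invalid.append(
            InvalidValueRecord(
                subject_key=subject_key,
                path=instance.path,
                repeat_keys=instance.repeat_keys,
                raw_value=instance.value,
                reason=InvalidReason(
                    UNDEFINED_REFERENCE,
                    f"no {instance.level} defined at this position",
                ),
            )
        )
        return None
    if instance.level == "item":
        if instance.value is None:
            return replace(instance, children=[], typed=None)
        result = validate_value(element.definition, instance.value)
        if isinstance(result, InvalidReason):
            invalid.append(
                InvalidValueRecord(
                    subject_key=subject_key,
                    path=instance.path,
                    repeat_keys=instance.repeat_keys,
                    raw_value=instance.value,
                    reason=result,
                )
            )
            return None
        return replace(
            instance, children=[], typed=replace(result, path=instance.path)
        )
    kept = []
    for child in instance.children:
        clean_child = _validate_instance(tree, subject_key, child, invalid)
        if clean_child is not None:
            kept.append(clean_child)
    return replace(instance, children=kept)


def validate_dataset(
    tree: MetadataTree, clinical: ClinicalDataset
) -> Tuple[ClinicalDataset, List[InvalidValueRecord]]:
    """Resolve and type-check every clinical instance.

    Returns a cleaned dataset containing exactly the instances that
    validated, plus one record per exclusion.  Unresolvable non-leaf paths
    yield a single record and drop the whole subtree beneath them.
    """
    invalid: List[InvalidValueRecord] = []
    clean_subjects = []
    for subject in clinical.subjects:
        kept = []
        for instance in subject.instances:
            clean = _validate_instance(tree, subject.subject_key, instance, invalid)
            if clean is not None:
                kept.append(clean)
        clean_subjects.append(
            SubjectRecord(subject_key=subject.subject_key, instances=kept)
        )
    return ClinicalDataset(subjects=clean_subjects), invalid


_CSV_HEADER = [
    "subject_key", "study_event_oid", "event_repeat_key", "form_oid",
    "form_repeat_key", "itemgroup_oid", "group_repeat_key", "item_oid",
    "raw_value", "reason", "detail",
]

_LEVEL_COLUMN = {"study_event": 1, "form": 3, "item_group": 5, "item": 7}
_KEY_COLUMN = {"study_event": 2, "form": 4, "item_group": 6}


def export_invalid_csv(invalid: List[InvalidValueRecord], sink) -> int:
    """Write the invalid-value list as RFC 4180 CSV (UTF-8, header row).

    ``sink`` may be a path or a text file object.  Returns the number of
    data rows written.
    """
    if isinstance(sink, (str, bytes)):
        with open(sink, "w", encoding="utf-8", newline="") as fh:
            return export_invalid_csv(invalid, fh)
    writer = csv.writer(sink, lineterminator="\r\n")
    writer.writerow(_CSV_HEADER)
    for rec in invalid:
        row = [""] * len(_CSV_HEADER)
        row[0] = rec.subject_key
        for depth, oid in enumerate(rec.path):
            level = ("study_event", "form", "item_group", "item")[depth]
            row[_LEVEL_COLUMN[level]] = str(oid)
        for level, key in rec.repeat_keys:
            row[_KEY_COLUMN[level]] = key
        row[8] = rec.raw_value if rec.raw_value is not None else ""
        row[9] = rec.reason.code
        row[10] = rec.reason.detail
        writer.writerow(row)
    return len(invalid)
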