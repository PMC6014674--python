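"""Synthetic ODM 1.3.2 fixtures with ground-truth manifests.

No public study exports exist for this kind of tool, so every other module
is tested against generated files.  :func:`generate` emits a complete ODM
document from a :class:`FixtureSpec` together with a :class:`Manifest`
holding independently computed ground truth (per-path counts, per-item
value multisets and naive summaries, completeness tallies for both modes,
and a ledger of injected errors).  The manifest bookkeeping is deliberately
written as plain nested loops over the generator's own records — it never
calls the parser, validator or statistics code it is used to check.

:func:`reference_scenarios` emits fixed handcrafted files encoding known
worked examples (the 5-repeat/2-filled mandatory-date case, one scenario
per category's example output, the bar-chart "others" rule, flag-free
completeness).
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple
from xml.etree import ElementTree as ET

ODM_NS = "http://www.cdisc.org/ns/odm/v1.3"

_WORDS = (
    "red", "green", "blue", "yellow", "violet", "amber", "teal", "coral",
    "ochre", "slate", "ivory", "sepia",
)

_TYPE_POOL = (
    "boolean", "integer", "float", "double", "string", "text",
    "date", "time", "datetime", "codelist",
)

INJECTABLE_REASONS = (
    "TYPE_MISMATCH", "NOT_IN_CODELIST", "UNDEFINED_REFERENCE", "UNSUPPORTED_TYPE",
)

STRUCTURAL_FAULTS = (
    "foreign_namespace", "missing_oid", "bad_version", "unknown_element",
    "malformed",
)


class SpecError(ValueError):
    """The fixture spec is infeasible or inconsistent."""


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 0
    subjects: int = 5
    events: int = 1
    forms_per_event: int = 1
    groups_per_form: int = 1
    items_per_group: int = 3
    type_weights: Optional[Dict[str, float]] = None
    codelist_size: Tuple[int, int] = (3, 6)
    repeat_prob: float = 0.0
    max_repeats: int = 3
    missing_rate: float = 0.0
    mandatory_density: float = 0.5
    invalid_plan: Tuple[Tuple[str, int], ...] = ()
    structural_faults: Tuple[str, ...] = ()
    reuse_form_across_events: bool = False

    def check(self) -> None:
        for rate in (self.repeat_prob, self.missing_rate, self.mandatory_density):
            if not 0.0 <= rate <= 1.0:
                raise SpecError(f"rate {rate} outside [0, 1]")
        for n in (self.subjects, self.events, self.forms_per_event,
                  self.groups_per_form, self.items_per_group):
            if n < 0:
                raise SpecError("negative structure count")
        if self.codelist_size[0] < 1 or self.codelist_size[0] > self.codelist_size[1]:
            raise SpecError(f"bad codelist size range {self.codelist_size}")
        if self.max_repeats < 1:
            raise SpecError("max_repeats must be >= 1")
        for reason, count in self.invalid_plan:
            if reason not in INJECTABLE_REASONS:
                raise SpecError(f"unknown injection reason {reason!r}")
            if count < 0:
                raise SpecError("negative injection count")
        for fault in self.structural_faults:
            if fault not in STRUCTURAL_FAULTS:
                raise SpecError(f"unknown structural fault {fault!r}")
        if self.reuse_form_across_events and self.events < 2:
            raise SpecError("form reuse requires at least two events")


@dataclass
class Manifest:
    """Ground truth for one generated file."""

    subjects: List[str]
    # path (tuple of OIDs) -> facts
    elements: Dict[tuple, dict] = field(default_factory=dict)
    items: Dict[tuple, dict] = field(default_factory=dict)
    completeness: Dict[str, dict] = field(default_factory=dict)
    injected: List[dict] = field(default_factory=list)

    def injected_counts(self) -> Dict[str, int]:
        out: Dict[str, int] = {}
        for rec in self.injected:
            out[rec["reason"]] = out.get(rec["reason"], 0) + 1
        return out


# ---------------------------------------------------------------------------
# Internal generator records (independent of the package's domain model)


@dataclass
class _GCodeList:
    oid: str
    data_type: str
    options: List[Tuple[str, str]]


@dataclass
class _GItem:
    oid: str
    name: str
    data_type: str
    codelist: Optional[str] = None


@dataclass
class _GNode:  # event / form / group definition
    oid: str
    name: str
    level: str
    repeating: bool = False
    refs: List[Tuple[str, bool]] = field(default_factory=list)  # (oid, mandatory)


@dataclass
class _GMeta:
    events: List[Tuple[str, bool]] = field(default_factory=list)
    nodes: Dict[str, _GNode] = field(default_factory=dict)
    items: Dict[str, _GItem] = field(default_factory=dict)
    codelists: Dict[str, _GCodeList] = field(default_factory=dict)


@dataclass
class _GItemInst:
    oid: str
    value: Optional[str]  # None = tag present with empty value
    emitted: bool = True  # False = tag omitted entirely
    invalid: Optional[str] = None  # injection reason
    undefined: bool = False  # injected ItemData with an undefined OID


@dataclass
class _GInst:
    oid: str
    repeat_key: Optional[str]
    children: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# Metadata / data generation


def _gen_metadata(spec: FixtureSpec, rng: random.Random) -> _GMeta:
    meta = _GMeta()
    weights = spec.type_weights or {t: 1.0 for t in _TYPE_POOL}
    pool = [t for t in _TYPE_POOL if weights.get(t, 0) > 0]
    wts = [weights[t] for t in pool]
    repeating = spec.repeat_prob > 0.0

    def mand() -> bool:
        return rng.random() < spec.mandatory_density

    item_counter = cl_counter = 0
    for e in range(1, spec.events + 1):
        ev = _GNode(oid=f"SE{e}", name=f"Event {e}", level="study_event",
                    repeating=repeating)
        meta.nodes[ev.oid] = ev
        meta.events.append((ev.oid, mand()))
        if spec.reuse_form_across_events and e > 1:
            # re-reference the first event's forms: positional distinctness
            first = meta.nodes["SE1"]
            ev.refs = [(oid, mand()) for oid, _ in first.refs]
            continue
        for f in range(1, spec.forms_per_event + 1):
            fo = _GNode(oid=f"F{e}_{f}", name=f"Form {e}.{f}", level="form",
                        repeating=repeating)
            meta.nodes[fo.oid] = fo
            ev.refs.append((fo.oid, mand()))
            for g in range(1, spec.groups_per_form + 1):
                gr = _GNode(oid=f"IG{e}_{f}_{g}", name=f"Group {e}.{f}.{g}",
                            level="item_group", repeating=repeating)
                meta.nodes[gr.oid] = gr
                fo.refs.append((gr.oid, mand()))
                for _ in range(spec.items_per_group):
                    item_counter += 1
                    dtype = rng.choices(pool, weights=wts, k=1)[0]
                    clref = None
                    if dtype == "codelist":
                        cl_counter += 1
                        size = rng.randint(*spec.codelist_size)
                        clref = f"CL{cl_counter}"
                        meta.codelists[clref] = _GCodeList(
                            oid=clref, data_type="string",
                            options=[(f"C{i}", f"Choice {i}") for i in range(1, size + 1)],
                        )
                        dtype = "string"
                    item = _GItem(oid=f"I{item_counter}", name=f"Item {item_counter}",
                                  data_type=dtype, codelist=clref)
                    meta.items[item.oid] = item
                    gr.refs.append((item.oid, mand()))
    return meta


def _gen_value(item: _GItem, meta: _GMeta, rng: random.Random) -> str:
    if item.codelist:
        return rng.choice(meta.codelists[item.codelist].options)[0]
    t = item.data_type
    if t == "boolean":
        return rng.choice(("true", "false", "1", "0"))
    if t == "integer":
        return str(rng.randint(-50, 200))
    if t in ("float", "double"):
        return f"{rng.uniform(-10.0, 100.0):.2f}"
    if t in ("string", "text"):
        return rng.choice(_WORDS)
    if t == "date":
        y, m, d = rng.randint(1950, 2020), rng.randint(1, 12), rng.randint(1, 28)
        return f"{y:04d}-{m:02d}-{d:02d}"
    if t == "time":
        return f"{rng.randint(0, 23):02d}:{rng.randint(0, 59):02d}:{rng.randint(0, 59):02d}"
    if t == "datetime":
        y, m, d = rng.randint(1950, 2020), rng.randint(1, 12), rng.randint(1, 28)
        return (f"{y:04d}-{m:02d}-{d:02d}T{rng.randint(0, 23):02d}:"
                f"{rng.randint(0, 59):02d}:{rng.randint(0, 59):02d}")
    raise SpecError(f"no value generator for data type {t!r}")


def _n_repeats(spec: FixtureSpec, repeating: bool, rng: random.Random) -> int:
    if not repeating or spec.max_repeats == 1:
        return 1
    if rng.random() < spec.repeat_prob:
        return 1 + rng.randint(1, spec.max_repeats - 1)
    return 1


def _gen_subject(spec: FixtureSpec, meta: _GMeta, rng: random.Random) -> List[_GInst]:
    events = []
    for ev_oid, _ in meta.events:
        ev_def = meta.nodes[ev_oid]
        for r in range(_n_repeats(spec, ev_def.repeating, rng)):
            ev = _GInst(oid=ev_oid,
                        repeat_key=str(r + 1) if ev_def.repeating else None)
            events.append(ev)
            for fo_oid, _ in ev_def.refs:
                fo_def = meta.nodes[fo_oid]
                for fr in range(_n_repeats(spec, fo_def.repeating, rng)):
                    fo = _GInst(oid=fo_oid,
                                repeat_key=str(fr + 1) if fo_def.repeating else None)
                    ev.children.append(fo)
                    for gr_oid, _ in fo_def.refs:
                        gr_def = meta.nodes[gr_oid]
                        for gr_r in range(_n_repeats(spec, gr_def.repeating, rng)):
                            gr = _GInst(
                                oid=gr_oid,
                                repeat_key=str(gr_r + 1) if gr_def.repeating else None,
                            )
                            fo.children.append(gr)
                            for it_oid, _ in gr_def.refs:
                                item = meta.items[it_oid]
                                if rng.random() < spec.missing_rate:
                                    if rng.random() < 0.5:
                                        gr.children.append(
                                            _GItemInst(oid=it_oid, value=None,
                                                       emitted=False)
                                        )
                                    else:
                                        gr.children.append(
                                            _GItemInst(oid=it_oid, value=None)
                                        )
                                else:
                                    gr.children.append(
                                        _GItemInst(
                                            oid=it_oid,
                                            value=_gen_value(item, meta, rng),
                                        )
                                    )
    return events


# ---------------------------------------------------------------------------
# Error injection


_MISMATCH_TOKEN = "<not-convertible>"
_OFF_LIST_TOKEN = "__NOT_IN_LIST__"
_UNDEFINED_OID = "UNDEF_ITEM"
_PARTIAL_ITEM_OID = "I_PARTIAL"


def _iter_groups(subjects: Dict[str, List[_GInst]]):
    for key in sorted(subjects):
        for ev in subjects[key]:
            for fo in ev.children:
                for gr in fo.children:
                    yield key, gr


def _inject(
    spec: FixtureSpec,
    meta: _GMeta,
    subjects: Dict[str, List[_GInst]],
    rng: random.Random,
    ledger: List[dict],
) -> None:
    plan = {reason: count for reason, count in spec.invalid_plan}
    if plan.get("UNSUPPORTED_TYPE"):
        # one extra item of a structurally legal but unimplemented type
        groups = [n for n in meta.nodes.values() if n.level == "item_group"]
        if not groups:
            raise SpecError("UNSUPPORTED_TYPE injections need an item group")
        meta.items[_PARTIAL_ITEM_OID] = _GItem(
            oid=_PARTIAL_ITEM_OID, name="Partial date item",
            data_type="partialDate",
        )
        groups[0].refs.append((_PARTIAL_ITEM_OID, False))
    for reason in ("TYPE_MISMATCH", "NOT_IN_CODELIST"):
        need = plan.get(reason, 0)
        if not need:
            continue
        candidates = []
        for key, gr in _iter_groups(subjects):
            for inst in gr.children:
                if not inst.emitted or inst.value is None or inst.invalid:
                    continue
                item = meta.items[inst.oid]
                if reason == "NOT_IN_CODELIST" and item.codelist:
                    candidates.append((key, inst))
                elif (reason == "TYPE_MISMATCH" and not item.codelist
                        and item.data_type not in ("string", "text")):
                    candidates.append((key, inst))
        if len(candidates) < need:
            raise SpecError(
                f"cannot place {need} {reason} injections "
                f"({len(candidates)} candidate values)"
            )
        for key, inst in rng.sample(candidates, need):
            inst.invalid = reason
            inst.value = (
                _OFF_LIST_TOKEN if reason == "NOT_IN_CODELIST" else _MISMATCH_TOKEN
            )
            ledger.append({"reason": reason, "subject": key, "item_oid": inst.oid,
                           "raw": inst.value})
    need = plan.get("UNDEFINED_REFERENCE", 0)
    if need:
        spots = [(key, gr) for key, gr in _iter_groups(subjects)]
        if not spots:
            raise SpecError("no item groups to host UNDEFINED_REFERENCE injections")
        for i in range(need):
            key, gr = spots[rng.randrange(len(spots))]
            inst = _GItemInst(oid=_UNDEFINED_OID, value="1", undefined=True)
            gr.children.append(inst)
            ledger.append({"reason": "UNDEFINED_REFERENCE", "subject": key,
                           "item_oid": _UNDEFINED_OID, "raw": "1"})
    need = plan.get("UNSUPPORTED_TYPE", 0)
    if need:
        host_group = next(
            n.oid for n in meta.nodes.values() if n.level == "item_group"
        )
        spots = [(key, gr) for key, gr in _iter_groups(subjects)
                 if gr.oid == host_group]
        if not spots:
            raise SpecError("no host group instances for UNSUPPORTED_TYPE injections")
        for i in range(need):
            key, gr = spots[rng.randrange(len(spots))]
            inst = _GItemInst(oid=_PARTIAL_ITEM_OID, value="2020-01",
                              invalid="UNSUPPORTED_TYPE")
            gr.children.append(inst)
            ledger.append({"reason": "UNSUPPORTED_TYPE", "subject": key,
                           "item_oid": _PARTIAL_ITEM_OID, "raw": "2020-01"})


# ---------------------------------------------------------------------------
# Manifest (independent ground-truth bookkeeping)


def _positional_paths(meta: _GMeta):
    """Yield (path, level, mandatory, def_oid) in metadata order."""
    for ev_oid, ev_mand in meta.events:
        yield (ev_oid,), "study_event", ev_mand, ev_oid
        ev = meta.nodes[ev_oid]
        for fo_oid, fo_mand in ev.refs:
            yield (ev_oid, fo_oid), "form", fo_mand, fo_oid
            fo = meta.nodes[fo_oid]
            for gr_oid, gr_mand in fo.refs:
                yield (ev_oid, fo_oid, gr_oid), "item_group", gr_mand, gr_oid
                gr = meta.nodes[gr_oid]
                for it_oid, it_mand in gr.refs:
                    yield (ev_oid, fo_oid, gr_oid, it_oid), "item", it_mand, it_oid


def _clean_item_exists(inst: _GItemInst) -> bool:
    """Does this item instance survive semantic validation?"""
    return inst.emitted and not inst.invalid and not inst.undefined


def _naive_summary(category: str, values: List[str], meta: _GMeta,
                   item: _GItem) -> Optional[dict]:
    if not values:
        return None
    if category == "dichotomous":
        t = sum(1 for v in values if v in ("true", "1"))
        return {"true": t, "false": len(values) - t}
    if category in ("nominal", "ordinal"):
        counts: Dict[str, int] = {}
        for v in values:
            counts[v] = counts.get(v, 0) + 1
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:3]
        out = {"top": ranked, "diversity": len(counts)}
        if category == "ordinal":
            out["diversity_total"] = len(meta.codelists[item.codelist].options)
        return out
    if category == "interval":
        return {"min": min(values), "max": max(values), "n": len(values)}
    nums = [float(v) for v in values]
    n = len(nums)
    mean = sum(nums) / n
    ordered = sorted(nums)
    mid = n // 2
    median = ordered[mid] if n % 2 else (ordered[mid - 1] + ordered[mid]) / 2.0
    var = sum((x - mean) ** 2 for x in nums) / (n - 1) if n > 1 else 0.0
    return {"min": min(nums), "max": max(nums), "mean": mean,
            "median": median, "stddev": math.sqrt(var), "n": n}


def _category_of(item: _GItem) -> Optional[str]:
    if item.codelist:
        return "ordinal"
    return {
        "boolean": "dichotomous", "string": "nominal", "text": "nominal",
        "integer": "ratio", "float": "ratio", "double": "ratio",
        "date": "interval", "time": "interval", "datetime": "interval",
    }.get(item.data_type)


def _complete_naive(
    level: str, inst, meta: _GMeta, refs: List[Tuple[str, bool]], all_mand: bool
) -> bool:
    if level == "item":
        return _clean_item_exists(inst) and inst.value is not None
    child_level = {"subject": "study_event", "study_event": "form",
                   "form": "item_group", "item_group": "item"}[level]
    children = inst if level == "subject" else inst.children
    for ref_oid, mandatory in refs:
        mine = [c for c in children if c.oid == ref_oid
                and (child_level != "item" or _clean_item_exists(c))]
        if (all_mand or mandatory) and not mine:
            return False
        for c in mine:
            child_refs = (meta.nodes[ref_oid].refs
                          if child_level != "item" else [])
            if not _complete_naive(child_level, c, meta, child_refs, all_mand):
                return False
    return True


def _manifest_completeness(
    meta: _GMeta, subjects: Dict[str, List[_GInst]], all_mand: bool
) -> dict:
    nodes: Dict[tuple, dict] = {
        path: {"expected": 0, "completed": 0}
        for path, _, _, _ in _positional_paths(meta)
    }
    completed_subjects = 0
    for key in sorted(subjects):
        events = subjects[key]
        if _complete_naive("subject", events, meta, meta.events, all_mand):
            completed_subjects += 1

        def walk(path, level, mandatory, parents, refs):
            child_level = {"study_event": "form", "form": "item_group",
                           "item_group": "item"}.get(level)
            groups = []
            for parent in parents:
                kids = [c for c in parent if c.oid == path[-1]] if level == "study_event" else [
                    c for c in parent.children if c.oid == path[-1]
                ]
                if level == "item":
                    kids = [c for c in kids if _clean_item_exists(c)]
                groups.append(kids)
            flat = [c for g in groups for c in g]
            node = nodes[path]
            node["expected"] += len(flat)
            if all_mand or mandatory:
                node["expected"] += sum(1 for g in groups if not g)
            node["completed"] += sum(
                1 for c in flat if _complete_naive(level, c, meta, refs, all_mand)
            )
            if child_level is None:
                return
            for ref_oid, ref_mand in refs:
                child_refs = (meta.nodes[ref_oid].refs
                              if child_level != "item" else [])
                walk(path + (ref_oid,), child_level, ref_mand, flat, child_refs)

        for ev_oid, ev_mand in meta.events:
            walk((ev_oid,), "study_event", ev_mand, [events],
                 meta.nodes[ev_oid].refs)
    return {
        "nodes": {path: dict(v) for path, v in nodes.items()},
        "completed_subjects": completed_subjects,
        "total_subjects": len(subjects),
    }


def _build_manifest(
    meta: _GMeta, subjects: Dict[str, List[_GInst]], ledger: List[dict]
) -> Manifest:
    manifest = Manifest(subjects=sorted(subjects))
    # collect clean instances per positional path, subject by subject
    per_path: Dict[tuple, List[str]] = {}
    values: Dict[tuple, List[str]] = {}
    repeats: Dict[tuple, bool] = {}
    for key in sorted(subjects):
        seen_here: Dict[tuple, int] = {}

        def note(path, subj):
            per_path.setdefault(path, []).append(subj)
            seen_here[path] = seen_here.get(path, 0) + 1

        for ev in subjects[key]:
            ev_path = (ev.oid,)
            note(ev_path, key)
            for fo in ev.children:
                fo_path = ev_path + (fo.oid,)
                note(fo_path, key)
                for gr in fo.children:
                    gr_path = fo_path + (gr.oid,)
                    note(gr_path, key)
                    for inst in gr.children:
                        if not _clean_item_exists(inst):
                            continue
                        it_path = gr_path + (inst.oid,)
                        note(it_path, key)
                        if inst.value is not None:
                            values.setdefault(it_path, []).append(inst.value)
        for path, count in seen_here.items():
            if count > 1:
                repeats[path] = True
    for path, level, mandatory, def_oid in _positional_paths(meta):
        refs = per_path.get(path, [])
        manifest.elements[path] = {
            "level": level,
            "mandatory": mandatory,
            "reference_count": len(refs),
            "subject_count": len(set(refs)),
            "repeat_flag": repeats.get(path, False),
        }
        if level == "item":
            item = meta.items[def_oid]
            category = _category_of(item)
            vals = sorted(values.get(path, []))
            manifest.items[path] = {
                "data_type": item.data_type,
                "category": category,
                "values": vals,
                "summary": (_naive_summary(category, values.get(path, []),
                                           meta, item)
                            if category else None),
            }
    manifest.completeness = {
        "mandatory_flag": _manifest_completeness(meta, subjects, False),
        "all_mandatory": _manifest_completeness(meta, subjects, True),
    }
    manifest.injected = list(ledger)
    return manifest


# ---------------------------------------------------------------------------
# XML emission


def _emit_xml(
    meta: _GMeta,
    subjects: Dict[str, List[_GInst]],
    faults: Sequence[str] = (),
    study_oid: str = "ST1",
    study_name: str = "Synthetic Study",
) -> bytes:
    ET.register_namespace("", ODM_NS)
    version = "1.2" if "bad_version" in faults else "1.3.2"
    root = ET.Element(f"{{{ODM_NS}}}ODM", {
        "ODMVersion": version, "FileOID": "FILE.1", "FileType": "Snapshot",
        "CreationDateTime": "2020-01-01T00:00:00",
    })
    study = ET.SubElement(root, f"{{{ODM_NS}}}Study", {"OID": study_oid})
    gv = ET.SubElement(study, f"{{{ODM_NS}}}GlobalVariables")
    ET.SubElement(gv, f"{{{ODM_NS}}}StudyName").text = study_name
    ET.SubElement(gv, f"{{{ODM_NS}}}StudyDescription").text = "Generated fixture"
    ET.SubElement(gv, f"{{{ODM_NS}}}ProtocolName").text = study_name
    mdv = ET.SubElement(study, f"{{{ODM_NS}}}MetaDataVersion",
                        {"OID": "MDV1", "Name": "Version 1"})
    protocol = ET.SubElement(mdv, f"{{{ODM_NS}}}Protocol")
    for i, (ev_oid, mand) in enumerate(meta.events, 1):
        ET.SubElement(protocol, f"{{{ODM_NS}}}StudyEventRef", {
            "StudyEventOID": ev_oid, "OrderNumber": str(i),
            "Mandatory": "Yes" if mand else "No",
        })
    if "foreign_namespace" in faults:
        ET.SubElement(mdv, "{http://example.org/ext}Extra")
    if "unknown_element" in faults:
        ET.SubElement(mdv, f"{{{ODM_NS}}}Bogus")

    def _defs(level):
        return [n for n in meta.nodes.values() if n.level == level]

    for ev in _defs("study_event"):
        el = ET.SubElement(mdv, f"{{{ODM_NS}}}StudyEventDef", {
            "OID": ev.oid, "Name": ev.name,
            "Repeating": "Yes" if ev.repeating else "No", "Type": "Scheduled",
        })
        for i, (oid, mand) in enumerate(ev.refs, 1):
            ET.SubElement(el, f"{{{ODM_NS}}}FormRef", {
                "FormOID": oid, "OrderNumber": str(i),
                "Mandatory": "Yes" if mand else "No",
            })
    for fo in _defs("form"):
        el = ET.SubElement(mdv, f"{{{ODM_NS}}}FormDef", {
            "OID": fo.oid, "Name": fo.name,
            "Repeating": "Yes" if fo.repeating else "No",
        })
        for i, (oid, mand) in enumerate(fo.refs, 1):
            ET.SubElement(el, f"{{{ODM_NS}}}ItemGroupRef", {
                "ItemGroupOID": oid, "OrderNumber": str(i),
                "Mandatory": "Yes" if mand else "No",
            })
    for gr in _defs("item_group"):
        el = ET.SubElement(mdv, f"{{{ODM_NS}}}ItemGroupDef", {
            "OID": gr.oid, "Name": gr.name,
            "Repeating": "Yes" if gr.repeating else "No",
        })
        for i, (oid, mand) in enumerate(gr.refs, 1):
            ET.SubElement(el, f"{{{ODM_NS}}}ItemRef", {
                "ItemOID": oid, "OrderNumber": str(i),
                "Mandatory": "Yes" if mand else "No",
            })
    for i, item in enumerate(meta.items.values()):
        attrs = {"OID": item.oid, "Name": item.name, "DataType": item.data_type}
        if "missing_oid" in faults and i == 0:
            del attrs["OID"]
        el = ET.SubElement(mdv, f"{{{ODM_NS}}}ItemDef", attrs)
        q = ET.SubElement(el, f"{{{ODM_NS}}}Question")
        ET.SubElement(q, f"{{{ODM_NS}}}TranslatedText").text = f"{item.name}?"
        if item.codelist:
            ET.SubElement(el, f"{{{ODM_NS}}}CodeListRef",
                          {"CodeListOID": item.codelist})
    for cl in meta.codelists.values():
        el = ET.SubElement(mdv, f"{{{ODM_NS}}}CodeList", {
            "OID": cl.oid, "Name": cl.oid, "DataType": cl.data_type,
        })
        for code, decode in cl.options:
            item_el = ET.SubElement(el, f"{{{ODM_NS}}}CodeListItem",
                                    {"CodedValue": code})
            dec = ET.SubElement(item_el, f"{{{ODM_NS}}}Decode")
            ET.SubElement(dec, f"{{{ODM_NS}}}TranslatedText").text = decode

    cd = ET.SubElement(root, f"{{{ODM_NS}}}ClinicalData",
                       {"StudyOID": study_oid, "MetaDataVersionOID": "MDV1"})
    for key in sorted(subjects):
        sd = ET.SubElement(cd, f"{{{ODM_NS}}}SubjectData", {"SubjectKey": key})
        for ev in subjects[key]:
            ev_attrs = {"StudyEventOID": ev.oid}
            if ev.repeat_key is not None:
                ev_attrs["StudyEventRepeatKey"] = ev.repeat_key
            ev_el = ET.SubElement(sd, f"{{{ODM_NS}}}StudyEventData", ev_attrs)
            for fo in ev.children:
                fo_attrs = {"FormOID": fo.oid}
                if fo.repeat_key is not None:
                    fo_attrs["FormRepeatKey"] = fo.repeat_key
                fo_el = ET.SubElement(ev_el, f"{{{ODM_NS}}}FormData", fo_attrs)
                for gr in fo.children:
                    gr_attrs = {"ItemGroupOID": gr.oid}
                    if gr.repeat_key is not None:
                        gr_attrs["ItemGroupRepeatKey"] = gr.repeat_key
                    gr_el = ET.SubElement(fo_el, f"{{{ODM_NS}}}ItemGroupData",
                                          gr_attrs)
                    for inst in gr.children:
                        if not inst.emitted:
                            continue
                        attrs = {"ItemOID": inst.oid}
                        attrs["Value"] = inst.value if inst.value is not None else ""
                        ET.SubElement(gr_el, f"{{{ODM_NS}}}ItemData", attrs)
    payload = ET.tostring(root, encoding="UTF-8", xml_declaration=True)
    if "malformed" in faults:
        payload = payload[:-20]
    return payload


# ---------------------------------------------------------------------------
# Public API


def generate(spec: FixtureSpec) -> Tuple[bytes, Manifest]:
    """Emit one ODM file plus its ground-truth manifest.

    Deterministic: the same spec (same seed) yields identical bytes and an
    identical manifest.
    """
    spec.check()
    rng = random.Random(spec.seed)
    meta = _gen_metadata(spec, rng)
    subjects = {
        f"S{i:04d}": _gen_subject(spec, meta, rng)
        for i in range(1, spec.subjects + 1)
    }
    ledger: List[dict] = []
    _inject(spec, meta, subjects, rng, ledger)
    manifest = _build_manifest(meta, subjects, ledger)
    payload = _emit_xml(meta, subjects, faults=spec.structural_faults)
    return payload, manifest


@dataclass(frozen=True)
class Scenario:
    name: str
    xml: bytes
    expected: dict


def _single_item_meta(item: _GItem, codelist: Optional[_GCodeList] = None,
                      group_repeating: bool = False,
                      item_mandatory: bool = False) -> _GMeta:
    meta = _GMeta()
    meta.events.append(("SE1", False))
    meta.nodes["SE1"] = _GNode(oid="SE1", name="Event", level="study_event",
                               refs=[("F1", False)])
    meta.nodes["F1"] = _GNode(oid="F1", name="Form", level="form",
                              refs=[("IG1", False)])
    meta.nodes["IG1"] = _GNode(oid="IG1", name="Group", level="item_group",
                               repeating=group_repeating,
                               refs=[(item.oid, item_mandatory)])
    meta.items[item.oid] = item
    if codelist is not None:
        meta.codelists[codelist.oid] = codelist
    return meta


def _single_item_subjects(values: List[Optional[str]],
                          one_subject_repeats: bool = False) -> Dict[str, List[_GInst]]:
    """One value per subject, or all values as repeated groups of subject 1."""
    subjects: Dict[str, List[_GInst]] = {}
    if one_subject_repeats:
        gr_list = []
        for i, v in enumerate(values, 1):
            gr = _GInst(oid="IG1", repeat_key=str(i))
            if v is not None:
                gr.children.append(_GItemInst(oid="I1", value=v))
            gr_list.append(gr)
        fo = _GInst(oid="F1", repeat_key=None, children=gr_list)
        ev = _GInst(oid="SE1", repeat_key=None, children=[fo])
        subjects["S0001"] = [ev]
        return subjects
    for i, v in enumerate(values, 1):
        gr = _GInst(oid="IG1", repeat_key=None)
        if v is not None:
            gr.children.append(_GItemInst(oid="I1", value=v))
        fo = _GInst(oid="F1", repeat_key=None, children=[gr])
        ev = _GInst(oid="SE1", repeat_key=None, children=[fo])
        subjects[f"S{i:04d}"] = [ev]
    return subjects


def reference_scenarios() -> List[Scenario]:
    """Fixed fixtures encoding the printed worked examples."""
    scenarios: List[Scenario] = []

    # 1. mandatory date item, group instantiated 5x, value present twice
    item = _GItem(oid="I1", name="Event date", data_type="date")
    meta = _single_item_meta(item, group_repeating=True, item_mandatory=True)
    values = ["2019-03-01", "2019-04-01", None, None, None]
    subjects = _single_item_subjects(values, one_subject_repeats=True)
    scenarios.append(Scenario(
        name="completeness_worked_example",
        xml=_emit_xml(meta, subjects),
        expected={
            "item_path": ("SE1", "F1", "IG1", "I1"),
            "group_path": ("SE1", "F1", "IG1"),
            "item_percentage": 40.0,
            "item_expected": 5, "item_completed": 2,
            "group_expected": 5, "group_completed": 2,
        },
    ))

    # 2. codelist with 15 options, all observed -> 9 bars + "others"
    cl = _GCodeList(oid="CL1", data_type="string",
                    options=[(f"O{i:02d}", f"Option {i}") for i in range(1, 16)])
    item = _GItem(oid="I1", name="Large list", data_type="string", codelist="CL1")
    meta = _single_item_meta(item, codelist=cl)
    vals: List[Optional[str]] = []
    for i in range(1, 16):
        vals.extend([f"O{i:02d}"] * (16 - i))  # option i observed (16 - i) times
    subjects = _single_item_subjects(vals)
    scenarios.append(Scenario(
        name="ordinal_others_rule",
        xml=_emit_xml(meta, subjects),
        expected={"item_path": ("SE1", "F1", "IG1", "I1"),
                  "n_values": len(vals), "bars": 10, "labelled": 9},
    ))

    # 3. Yes/No/Maybe with counts 8/4/3
    cl = _GCodeList(oid="CL1", data_type="string",
                    options=[("Yes", "Yes"), ("No", "No"), ("Maybe", "Maybe")])
    item = _GItem(oid="I1", name="Tristate", data_type="string", codelist="CL1")
    meta = _single_item_meta(item, codelist=cl)
    subjects = _single_item_subjects(["Yes"] * 8 + ["No"] * 4 + ["Maybe"] * 3)
    scenarios.append(Scenario(
        name="ordinal_yes_no_maybe",
        xml=_emit_xml(meta, subjects),
        expected={"item_path": ("SE1", "F1", "IG1", "I1"),
                  "summary": "Diversity: 3/3 - Top3: 1. Yes (8) | 2. No (4) | 3. Maybe (3)"},
    ))

    # 4. boolean 55 true / 45 false
    item = _GItem(oid="I1", name="Flag", data_type="boolean")
    meta = _single_item_meta(item)
    subjects = _single_item_subjects(
        ["true"] * 30 + ["1"] * 25 + ["false"] * 25 + ["0"] * 20
    )
    scenarios.append(Scenario(
        name="dichotomous_55_45",
        xml=_emit_xml(meta, subjects),
        expected={"item_path": ("SE1", "F1", "IG1", "I1"),
                  "summary": "True: 55 - False: 45"},
    ))

    # 5. nominal: diversity 22, top3 red(9)/green(7)/blue(5)
    item = _GItem(oid="I1", name="Colour", data_type="string")
    meta = _single_item_meta(item)
    uniques = [f"shade-{i:02d}" for i in range(1, 20)]
    subjects = _single_item_subjects(
        ["red"] * 9 + ["green"] * 7 + ["blue"] * 5 + uniques
    )
    scenarios.append(Scenario(
        name="nominal_top3",
        xml=_emit_xml(meta, subjects),
        expected={"item_path": ("SE1", "F1", "IG1", "I1"),
                  "summary": ("Diversity: 22 - Top3: 1. red (9) | "
                              "2. green (7) | 3. blue (5)")},
    ))

    # 6. interval range over two datetimes
    item = _GItem(oid="I1", name="Timestamp", data_type="datetime")
    meta = _single_item_meta(item)
    subjects = _single_item_subjects(
        ["1920-05-05T13:54:47", "2010-06-09T20:11:59"]
    )
    scenarios.append(Scenario(
        name="interval_range",
        xml=_emit_xml(meta, subjects),
        expected={"item_path": ("SE1", "F1", "IG1", "I1"),
                  "summary": ("Range: 13:54:47 on 05 May 1920 - "
                              "20:11:59 on 09 June 2010")},
    ))

    # 7. ratio summary at one decimal
    item = _GItem(oid="I1", name="Score", data_type="float")
    meta = _single_item_meta(item)
    subjects = _single_item_subjects(
        ["1.1", "2.9", "4.1", "4.4", "5.9", "7.1", "8.8"]
    )
    scenarios.append(Scenario(
        name="ratio_summary",
        xml=_emit_xml(meta, subjects),
        expected={"item_path": ("SE1", "F1", "IG1", "I1"),
                  "summary": ("Min: 1.1 | Max: 8.8 | Mean: 4.9 | "
                              "Median: 4.4 | StdDev: 2.6")},
    ))

    # 8. no mandatory flags: sparse data, yet every subject complete
    item = _GItem(oid="I1", name="Optional note", data_type="string")
    meta = _single_item_meta(item, item_mandatory=False)
    subjects = _single_item_subjects(["hello", None, None, "there", None])
    scenarios.append(Scenario(
        name="no_mandatory_flags",
        xml=_emit_xml(meta, subjects),
        expected={"total_subjects": 5, "completed_subjects_flag": 5},
    ))

    # 9. all-mandatory reading of the same sparse study
    scenarios.append(Scenario(
        name="all_mandatory_sparse",
        xml=_emit_xml(meta, subjects),
        expected={"total_subjects": 5, "completed_subjects_all": 2},
    ))
    return scenarios
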