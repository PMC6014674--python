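"""Streaming reader for ODM-XML 1.3.x study exports.

Two passes over the document, both memory-bounded (peak memory scales with
the metadata size plus one subject's data, never with the file size):

1. :func:`validate_structure` — an explicit grammar for the supported ODM
   element subset, run over an expat stream so every finding carries a line
   number and an XML path.  Foreign-namespace elements or attributes are
   rejected as extensions.  Lexical forms of attributes are checked;
   semantic content is not.
2. :func:`parse_odm` — incremental construction of the
   :class:`~odm_insight.model.MetadataTree` and
   :class:`~odm_insight.model.ClinicalDataset`, run only when pass 1 found
   nothing.
"""

from __future__ import annotations

import io
import re
import xml.parsers.expat
from dataclasses import dataclass, field
from typing import BinaryIO, Dict, List, Optional, Tuple, Union
from xml.etree import ElementTree as ET

from .model import (
    ClinicalDataset,
    CodeListDef,
    DataType,
    DefinitionRegistry,
    ElementInstance,
    ElementRef,
    FormDef,
    ItemDef,
    ItemGroupDef,
    MetadataTree,
    ModelError,
    Oid,
    StudyEventDef,
    SubjectRecord,
    build_positional_tree,
)

ODM_NS = "http://www.cdisc.org/ns/odm/v1.3"
XML_NS = "http://www.w3.org/XML/1998/namespace"
SUPPORTED_VERSIONS = ("1.3.0", "1.3.1", "1.3.2")

_CHUNK = 1 << 16
_MAX_ERRORS = 200

#: Full ODM 1.3 lexical set for ItemDef/CodeList DataType attributes.  Types
#: outside the supported subset pass the structural gate and are flagged
#: later during semantic validation.
ODM_DATATYPE_TOKENS = frozenset(
    {"text", "integer", "float", "date", "time", "datetime", "string",
     "boolean", "double", "hexBinary", "base64Binary", "hexFloat",
     "base64Float", "partialDate", "partialTime", "partialDatetime",
     "durationDatetime", "intervalDatetime", "incompleteDatetime",
     "incompleteDate", "incompleteTime", "URI"}
)


class UnsupportedVersionError(Exception):
    pass


@dataclass(frozen=True)
class StructuralError:
    """One schema-level violation; carries a location for correction."""

    line: Optional[int]
    xml_path: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - convenience
        loc = f"line {self.line}" if self.line else "line ?"
        return f"{loc} at {self.xml_path or '/'}: {self.message}"


@dataclass
class ParseResult:
    version: Optional[str]
    metadata: Optional[MetadataTree]
    clinical: Optional[ClinicalDataset]
    structural_errors: List[StructuralError] = field(default_factory=list)
    warnings: List[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.structural_errors


# ---------------------------------------------------------------------------
# Grammar for the supported element subset.
#
# Children are (tag, min, max) in required document order; max=None means
# unbounded.  Attribute maps give per-attribute lexical validators (None =
# any string).

def _nonempty(v: str) -> bool:
    return bool(v)


def _yes_no(v: str) -> bool:
    return v in ("Yes", "No")


def _order_number(v: str) -> bool:
    return bool(re.fullmatch(r"[+-]?\d+", v))


def _datatype_token(v: str) -> bool:
    return v in ODM_DATATYPE_TOKENS


def _filetype(v: str) -> bool:
    return v in ("Snapshot", "Transactional")


_ANY = None

_GRAMMAR: Dict[str, dict] = {
    "ODM": {
        "required": {"ODMVersion": _nonempty, "FileOID": _nonempty,
                     "FileType": _filetype, "CreationDateTime": _nonempty},
        "optional": {"Description": _ANY, "Granularity": _ANY,
                     "AsOfDateTime": _ANY, "Originator": _ANY, "SourceSystem": _ANY,
                     "SourceSystemVersion": _ANY, "PriorFileOID": _ANY, "Archival": _ANY,
                     "Id": _ANY},
        "children": [("Study", 0, None), ("ClinicalData", 0, None)],
    },
    "Study": {
        "required": {"OID": _nonempty},
        "optional": {},
        "children": [("GlobalVariables", 1, 1), ("MetaDataVersion", 0, None)],
    },
    "GlobalVariables": {
        "required": {}, "optional": {},
        "children": [("StudyName", 1, 1), ("StudyDescription", 1, 1),
                     ("ProtocolName", 1, 1)],
    },
    "StudyName": {"required": {}, "optional": {}, "children": [], "text": True},
    "StudyDescription": {"required": {}, "optional": {}, "children": [], "text": True},
    "ProtocolName": {"required": {}, "optional": {}, "children": [], "text": True},
    "MetaDataVersion": {
        "required": {"OID": _nonempty, "Name": _nonempty},
        "optional": {"Description": _ANY},
        "children": [("Protocol", 0, 1), ("StudyEventDef", 0, None),
                     ("FormDef", 0, None), ("ItemGroupDef", 0, None),
                     ("ItemDef", 0, None), ("CodeList", 0, None)],
    },
    "Protocol": {
        "required": {}, "optional": {},
        "children": [("Description", 0, 1), ("StudyEventRef", 0, None)],
    },
    "StudyEventRef": {
        "required": {"StudyEventOID": _nonempty, "Mandatory": _yes_no},
        "optional": {"OrderNumber": _order_number,
                     "CollectionExceptionConditionOID": _ANY},
        "children": [],
    },
    "StudyEventDef": {
        "required": {"OID": _nonempty, "Name": _nonempty, "Repeating": _yes_no,
                     "Type": lambda v: v in ("Scheduled", "Unscheduled", "Common")},
        "optional": {"Category": _ANY},
        "children": [("Description", 0, 1), ("FormRef", 0, None)],
    },
    "FormRef": {
        "required": {"FormOID": _nonempty, "Mandatory": _yes_no},
        "optional": {"OrderNumber": _order_number,
                     "CollectionExceptionConditionOID": _ANY},
        "children": [],
    },
    "FormDef": {
        "required": {"OID": _nonempty, "Name": _nonempty, "Repeating": _yes_no},
        "optional": {},
        "children": [("Description", 0, 1), ("ItemGroupRef", 0, None)],
    },
    "ItemGroupRef": {
        "required": {"ItemGroupOID": _nonempty, "Mandatory": _yes_no},
        "optional": {"OrderNumber": _order_number,
                     "CollectionExceptionConditionOID": _ANY},
        "children": [],
    },
    "ItemGroupDef": {
        "required": {"OID": _nonempty, "Name": _nonempty, "Repeating": _yes_no},
        "optional": {"IsReferenceData": _yes_no, "SASDatasetName": _ANY,
                     "Domain": _ANY, "Origin": _ANY, "Purpose": _ANY,
                     "Comment": _ANY},
        "children": [("Description", 0, 1), ("ItemRef", 0, None)],
    },
    "ItemRef": {
        "required": {"ItemOID": _nonempty, "Mandatory": _yes_no},
        "optional": {"OrderNumber": _order_number, "KeySequence": _order_number,
                     "MethodOID": _ANY, "Role": _ANY, "RoleCodeListOID": _ANY,
                     "CollectionExceptionConditionOID": _ANY},
        "children": [],
    },
    "ItemDef": {
        "required": {"OID": _nonempty, "Name": _nonempty,
                     "DataType": _datatype_token},
        "optional": {"Length": _order_number, "SignificantDigits": _order_number,
                     "SASFieldName": _ANY, "SDSVarName": _ANY, "Origin": _ANY,
                     "Comment": _ANY},
        "children": [("Description", 0, 1), ("Question", 0, 1),
                     ("CodeListRef", 0, 1)],
    },
    "Question": {
        "required": {}, "optional": {},
        "children": [("TranslatedText", 1, None)],
    },
    "Description": {
        "required": {}, "optional": {},
        "children": [("TranslatedText", 1, None)],
    },
    "TranslatedText": {"required": {}, "optional": {}, "children": [], "text": True},
    "CodeListRef": {
        "required": {"CodeListOID": _nonempty}, "optional": {}, "children": [],
    },
    "CodeList": {
        "required": {"OID": _nonempty, "Name": _nonempty,
                     "DataType": _datatype_token},
        "optional": {"SASFormatName": _ANY},
        "children": [("Description", 0, 1), ("CodeListItem", 0, None),
                     ("EnumeratedItem", 0, None)],
    },
    "CodeListItem": {
        "required": {"CodedValue": _nonempty}, "optional": {},
        "children": [("Decode", 1, 1)],
    },
    "EnumeratedItem": {
        "required": {"CodedValue": _nonempty}, "optional": {}, "children": [],
    },
    "Decode": {
        "required": {}, "optional": {},
        "children": [("TranslatedText", 1, None)],
    },
    "ClinicalData": {
        "required": {"StudyOID": _nonempty, "MetaDataVersionOID": _nonempty},
        "optional": {},
        "children": [("SubjectData", 0, None)],
    },
    "SubjectData": {
        "required": {"SubjectKey": _nonempty},
        "optional": {"TransactionType": _ANY},
        "children": [("StudyEventData", 0, None)],
    },
    "StudyEventData": {
        "required": {"StudyEventOID": _nonempty},
        "optional": {"StudyEventRepeatKey": _ANY, "TransactionType": _ANY},
        "children": [("FormData", 0, None)],
    },
    "FormData": {
        "required": {"FormOID": _nonempty},
        "optional": {"FormRepeatKey": _ANY, "TransactionType": _ANY},
        "children": [("ItemGroupData", 0, None)],
    },
    "ItemGroupData": {
        "required": {"ItemGroupOID": _nonempty},
        "optional": {"ItemGroupRepeatKey": _ANY, "TransactionType": _ANY},
        "children": [("ItemData", 0, None)],
    },
    "ItemData": {
        "required": {"ItemOID": _nonempty},
        "optional": {"Value": _ANY, "IsNull": _yes_no, "TransactionType": _ANY},
        "children": [],
    },
}


SourceT = Union[str, bytes, BinaryIO]


def _open_source(source: SourceT) -> BinaryIO:
    if isinstance(source, bytes):
        return io.BytesIO(source)
    if isinstance(source, str):
        return open(source, "rb")
    source.seek(0)
    return source


_DECL_ENCODING_RE = re.compile(rb"<\?xml[^>]*encoding\s*=\s*[\"']([^\"']+)[\"']")


def _check_encoding(head: bytes) -> Optional[str]:
    """Return an error message when the declared encoding is not UTF-8."""
    if head.startswith(b"\xff\xfe") or head.startswith(b"\xfe\xff"):
        return "unsupported character encoding (UTF-16 byte-order mark)"
    m = _DECL_ENCODING_RE.search(head[:256])
    if m and m.group(1).decode("ascii", "replace").lower() not in ("utf-8",):
        return f"unsupported character encoding {m.group(1).decode('ascii', 'replace')!r}"
    return None


class _StructureChecker:
    """expat-driven validator for the grammar above."""

    def __init__(self) -> None:
        self.errors: List[StructuralError] = []
        # stack entries: [tag, spec|None, last_child_group, counts, text_flagged]
        self._stack: List[list] = []
        self._foreign_depth = 0
        self.parser = xml.parsers.expat.ParserCreate(namespace_separator=" ")
        self.parser.StartElementHandler = self._start
        self.parser.EndElementHandler = self._end
        self.parser.CharacterDataHandler = self._chars
        self.parser.buffer_text = True

    # -- helpers

    def _path(self) -> str:
        return "/" + "/".join(frame[0] for frame in self._stack)

    def _err(self, message: str) -> None:
        if len(self.errors) < _MAX_ERRORS:
            self.errors.append(
                StructuralError(self.parser.CurrentLineNumber, self._path(), message)
            )

    # -- expat handlers

    def _start(self, name: str, attrs: Dict[str, str]) -> None:
        if self._foreign_depth:
            self._foreign_depth += 1
            return
        if " " in name:
            uri, tag = name.rsplit(" ", 1)
        else:
            uri, tag = "", name
        parent = self._stack[-1] if self._stack else None
        if uri != ODM_NS:
            self._stack_note_foreign(tag, uri)
            self._foreign_depth = 1
            return
        spec = _GRAMMAR.get(tag)
        if parent is None:
            if tag != "ODM":
                self._err(f"root element must be ODM, found {tag}")
                spec = None
        else:
            pspec = parent[1]
            if pspec is not None:
                groups = [c[0] for c in pspec["children"]]
                if tag not in groups:
                    self._err(f"element {tag} not allowed inside {parent[0]}")
                else:
                    idx = groups.index(tag)
                    if idx < parent[2]:
                        self._err(
                            f"element {tag} out of order inside {parent[0]}"
                        )
                    parent[2] = max(parent[2], idx)
                    parent[3][tag] = parent[3].get(tag, 0) + 1
                    _, _, mx = pspec["children"][idx]
                    if mx is not None and parent[3][tag] > mx:
                        self._err(
                            f"element {tag} appears more than {mx}x inside {parent[0]}"
                        )
        self._stack.append([tag, spec, -1, {}, False])
        if spec is not None:
            self._check_attrs(tag, spec, attrs)

    def _stack_note_foreign(self, tag: str, uri: str) -> None:
        self._err(
            f"foreign-namespace element {{{uri or 'no namespace'}}}{tag}: "
            "XML extensions are not allowed"
        )

    def _check_attrs(self, tag: str, spec: dict, attrs: Dict[str, str]) -> None:
        seen = set()
        for aname, aval in attrs.items():
            if " " in aname:
                auri, alocal = aname.rsplit(" ", 1)
                if auri == XML_NS:
                    continue  # xml:lang and friends
                self._err(
                    f"foreign-namespace attribute {alocal!r} on {tag}: "
                    "XML extensions are not allowed"
                )
                continue
            seen.add(aname)
            validator = spec["required"].get(aname, spec["optional"].get(aname, False))
            if validator is False:
                self._err(f"attribute {aname!r} not allowed on {tag}")
            elif callable(validator) and not validator(aval):
                self._err(f"attribute {aname}={aval!r} on {tag} has an invalid lexical form")
        for req in spec["required"]:
            if req not in seen:
                self._err(f"required attribute {req!r} missing on {tag}")

    def _end(self, name: str) -> None:
        if self._foreign_depth:
            self._foreign_depth -= 1
            return
        tag, spec, _, counts, _ = self._stack[-1]
        if spec is not None:
            for ctag, mn, _ in spec["children"]:
                if counts.get(ctag, 0) < mn:
                    self._err(f"element {tag} requires at least {mn} {ctag} child(ren)")
            if tag == "CodeList":
                if counts.get("CodeListItem", 0) + counts.get("EnumeratedItem", 0) == 0:
                    self._err("CodeList must contain at least one option")
        self._stack.pop()

    def _chars(self, data: str) -> None:
        if self._foreign_depth or not self._stack:
            return
        frame = self._stack[-1]
        spec = frame[1]
        if data.strip() and (spec is None or not spec.get("text")) and not frame[4]:
            frame[4] = True
            self._err(f"element {frame[0]} must not contain text content")


def detect_version(source: SourceT) -> str:
    """Read the declared ODM version from the document root.

    Raises :class:`UnsupportedVersionError` when the attribute is missing
    or outside the supported set.
    """
    stream = _open_source(source)
    try:
        head = stream.read(_CHUNK)
    finally:
        if isinstance(source, str):
            stream.close()
    m = re.search(rb"<(?:\w+:)?ODM\b[^>]*>", head, re.DOTALL)
    if m is None:
        raise UnsupportedVersionError("no ODM root element found")
    root = m.group(0)
    vm = re.search(rb"ODMVersion\s*=\s*[\"']([^\"']*)[\"']", root)
    if vm is None:
        raise UnsupportedVersionError("ODMVersion attribute missing")
    version = vm.group(1).decode("utf-8", "replace")
    if version not in SUPPORTED_VERSIONS:
        raise UnsupportedVersionError(f"unsupported ODM version {version!r}")
    return version


def validate_structure(source: SourceT) -> List[StructuralError]:
    """Validate a document against the supported-element grammar.

    Returns the (possibly empty) list of findings; never raises for
    document problems — a well-formedness failure becomes a finding too.
    """
    stream = _open_source(source)
    close = isinstance(source, str)
    try:
        head = stream.peek(256) if hasattr(stream, "peek") else b""
        if not head:
            pos = stream.tell()
            head = stream.read(256)
            stream.seek(pos)
        enc_err = _check_encoding(head)
        if enc_err:
            return [StructuralError(1, "/", enc_err)]
        checker = _StructureChecker()
        try:
            while True:
                chunk = stream.read(_CHUNK)
                if not chunk:
                    checker.parser.Parse(b"", True)
                    break
                checker.parser.Parse(chunk, False)
        except xml.parsers.expat.ExpatError as exc:
            checker.errors.append(
                StructuralError(getattr(exc, "lineno", None), "",
                                f"not well-formed XML: {exc}")
            )
        return checker.errors
    finally:
        if close:
            stream.close()


# ---------------------------------------------------------------------------
# Parsing pass


def _q(tag: str) -> str:
    return f"{{{ODM_NS}}}{tag}"


def _text_of(elem: ET.Element, *tags: str) -> Optional[str]:
    node = elem
    for tag in tags:
        node = node.find(_q(tag))
        if node is None:
            return None
    return (node.text or "").strip() or None


def _refs_of(elem: ET.Element, tag: str, oid_attr: str) -> Tuple[ElementRef, ...]:
    refs = []
    for i, ref in enumerate(elem.findall(_q(tag))):
        refs.append(
            ElementRef(
                target_oid=Oid(ref.get(oid_attr)),
                mandatory=ref.get("Mandatory") == "Yes",
                order=i,
            )
        )
    return tuple(refs)


def _build_registry(mdv: ET.Element) -> DefinitionRegistry:
    codelists = {}
    for cl in mdv.findall(_q("CodeList")):
        options = []
        for item in cl.findall(_q("CodeListItem")):
            decode = _text_of(item, "Decode", "TranslatedText") or ""
            options.append((item.get("CodedValue"), decode))
        for item in cl.findall(_q("EnumeratedItem")):
            options.append((item.get("CodedValue"), item.get("CodedValue")))
        oid = Oid(cl.get("OID"))
        codelists[oid] = CodeListDef(
            oid=oid, name=cl.get("Name"),
            data_type=DataType(cl.get("DataType")), options=tuple(options),
        )
    items = {}
    for it in mdv.findall(_q("ItemDef")):
        oid = Oid(it.get("OID"))
        clref = it.find(_q("CodeListRef"))
        codelist = None
        if clref is not None:
            codelist = codelists.get(Oid(clref.get("CodeListOID")))
            if codelist is None:
                raise ModelError(
                    f"item {oid} references undefined code list "
                    f"{clref.get('CodeListOID')!r}"
                )
        items[oid] = ItemDef(
            oid=oid, name=it.get("Name"), data_type=DataType(it.get("DataType")),
            question=_text_of(it, "Question", "TranslatedText"), codelist=codelist,
        )
    groups = {}
    for g in mdv.findall(_q("ItemGroupDef")):
        oid = Oid(g.get("OID"))
        groups[oid] = ItemGroupDef(
            oid=oid, name=g.get("Name"), repeating=g.get("Repeating") == "Yes",
            refs=_refs_of(g, "ItemRef", "ItemOID"),
        )
    forms = {}
    for f in mdv.findall(_q("FormDef")):
        oid = Oid(f.get("OID"))
        forms[oid] = FormDef(
            oid=oid, name=f.get("Name"), repeating=f.get("Repeating") == "Yes",
            refs=_refs_of(f, "ItemGroupRef", "ItemGroupOID"),
        )
    events = {}
    for e in mdv.findall(_q("StudyEventDef")):
        oid = Oid(e.get("OID"))
        events[oid] = StudyEventDef(
            oid=oid, name=e.get("Name"), repeating=e.get("Repeating") == "Yes",
            refs=_refs_of(e, "FormRef", "FormOID"),
        )
    return DefinitionRegistry(
        study_events=events, forms=forms, item_groups=groups,
        items=items, codelists=codelists,
    )


_REPEAT_ATTR = {
    "study_event": "StudyEventRepeatKey",
    "form": "FormRepeatKey",
    "item_group": "ItemGroupRepeatKey",
}

_DATA_LEVELS = (
    ("StudyEventData", "StudyEventOID", "study_event"),
    ("FormData", "FormOID", "form"),
    ("ItemGroupData", "ItemGroupOID", "item_group"),
)


def _build_instances(
    elem: ET.Element, depth: int, path: tuple, repeat_keys: tuple
) -> ElementInstance:
    tag, oid_attr, level = _DATA_LEVELS[depth]
    oid = Oid(elem.get(oid_attr))
    new_path = path + (oid,)
    rk = elem.get(_REPEAT_ATTR[level])
    new_keys = repeat_keys + (((level, rk),) if rk is not None else ())
    inst = ElementInstance(path=new_path, repeat_keys=new_keys)
    if depth + 1 < len(_DATA_LEVELS):
        child_tag = _q(_DATA_LEVELS[depth + 1][0])
        for child in elem:
            if child.tag == child_tag:
                inst.children.append(
                    _build_instances(child, depth + 1, new_path, new_keys)
                )
    else:
        for child in elem.findall(_q("ItemData")):
            value = child.get("Value")
            if value == "" or child.get("IsNull") == "Yes":
                value = None  # empty values are recorded as absent
            inst.children.append(
                ElementInstance(
                    path=new_path + (Oid(child.get("ItemOID")),),
                    repeat_keys=new_keys,
                    value=value,
                )
            )
    return inst


def parse_odm(source: SourceT) -> ParseResult:
    """Parse an ODM document after structural validation.

    When structural validation fails, the result carries the error list and
    no metadata or clinical data ("further analyses are aborted").  When
    the file declares several Study elements or MetaDataVersions, the first
    is used and a warning recorded.
    """
    try:
        version = detect_version(source)
    except UnsupportedVersionError as exc:
        return ParseResult(
            version=None, metadata=None, clinical=None,
            structural_errors=[StructuralError(1, "/ODM", str(exc))],
        )
    errors = validate_structure(source)
    if errors:
        return ParseResult(
            version=version, metadata=None, clinical=None, structural_errors=errors
        )

    warnings: List[str] = []
    stream = _open_source(source)
    close = isinstance(source, str)
    try:
        tree: Optional[MetadataTree] = None
        study_oid: Optional[str] = None
        study_name = ""
        mdv_seen = 0
        subjects: Dict[str, SubjectRecord] = {}
        study_count = 0
        in_first_study = False
        clinical_oid_ok = False
        for event, elem in ET.iterparse(stream, events=("start", "end")):
            if event == "start":
                if elem.tag == _q("Study"):
                    study_count += 1
                    in_first_study = study_count == 1
                    if in_first_study:
                        study_oid = elem.get("OID")
                    else:
                        warnings.append(
                            f"multiple Study elements; only the first "
                            f"({study_oid!r}) is analyzed"
                        )
                elif elem.tag == _q("ClinicalData"):
                    clinical_oid_ok = elem.get("StudyOID") == study_oid
                    if not clinical_oid_ok:
                        warnings.append(
                            f"ClinicalData for study {elem.get('StudyOID')!r} "
                            f"ignored (analyzing {study_oid!r})"
                        )
                continue
            if elem.tag == _q("GlobalVariables"):
                if in_first_study:
                    study_name = _text_of(elem, "StudyName") or ""
                elem.clear()
            elif elem.tag == _q("MetaDataVersion"):
                if in_first_study:
                    mdv_seen += 1
                    if mdv_seen == 1:
                        try:
                            registry = _build_registry(elem)
                            protocol = elem.find(_q("Protocol"))
                            study_refs = (
                                _refs_of(protocol, "StudyEventRef", "StudyEventOID")
                                if protocol is not None else ()
                            )
                            tree = build_positional_tree(
                                registry, study_refs, Oid(study_oid), study_name
                            )
                        except ModelError as exc:
                            return ParseResult(
                                version=version, metadata=None, clinical=None,
                                structural_errors=[
                                    StructuralError(
                                        None, "/ODM/Study/MetaDataVersion", str(exc)
                                    )
                                ],
                            )
                    else:
                        warnings.append(
                            "multiple MetaDataVersion elements; versions after "
                            "the first are ignored"
                        )
                elem.clear()
            elif elem.tag == _q("SubjectData"):
                if clinical_oid_ok:
                    key = elem.get("SubjectKey")
                    record = subjects.get(key)
                    if record is None:
                        record = SubjectRecord(subject_key=key)
                        subjects[key] = record
                    for ev in elem.findall(_q("StudyEventData")):
                        record.instances.append(_build_instances(ev, 0, (), ()))
                elem.clear()
        if study_count == 0:
            warnings.append("document contains no Study element")
        if tree is None:
            tree = MetadataTree(
                study_oid=Oid(study_oid) if study_oid else Oid("UNKNOWN"),
                study_name=study_name, events=(), registry=DefinitionRegistry(),
            )
        clinical = ClinicalDataset(subjects=list(subjects.values()))
        return ParseResult(
            version=version, metadata=tree, clinical=clinical,
            structural_errors=[], warnings=warnings,
        )
    finally:
        if close:
            stream.close()
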