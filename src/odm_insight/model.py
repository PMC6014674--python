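"""Domain model for hierarchical study metadata and subject data.

A study export carries two halves: *metadata* (the structure of the case
report forms: study events containing forms, forms containing item groups,
item groups containing items) and *clinical data* (per-subject values that
mirror that structure by OID reference).

Because one definition may be referenced from several places in the
hierarchy, every analysis in this package operates on *positional*
elements: one node per placement, identified by its full OID path.  A form
referenced under two study events therefore yields two distinct analyzable
elements.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Optional, Sequence, Tuple, Union

#: Hierarchy levels, root-most first.  ``LEVELS[len(path) - 1]`` gives the
#: level of a positional path.
LEVELS: Tuple[str, ...] = ("study_event", "form", "item_group", "item")

#: Data types with implemented statistics.  Rarer ODM lexical types (e.g.
#: partial dates) are structurally legal but semantically unsupported.
SUPPORTED_DATA_TYPES = frozenset(
    {"boolean", "string", "text", "integer", "float", "double",
     "date", "time", "datetime"}
)


class ModelError(Exception):
    """Base class for metadata-model construction failures."""


class MissingDefinitionError(ModelError):
    """A reference points at an OID with no definition of that class."""


class StructuralModelError(ModelError):
    """The reference graph violates a structural rule (e.g. a duplicate
    child OID under one parent)."""


class Oid(str):
    """Locally unique identifier token: non-empty, no whitespace."""

    __slots__ = ()

    def __new__(cls, value: str) -> "Oid":
        if not isinstance(value, str) or not value or any(c.isspace() for c in value):
            raise ValueError(f"invalid OID token: {value!r}")
        return str.__new__(cls, value)


PathT = Tuple[Oid, ...]
RepeatKeysT = Tuple[Tuple[str, str], ...]  # ((level, key), ...)


@dataclass(frozen=True)
class DataType:
    """Declared data type of an item, kept as the raw lexical token."""

    name: str

    @property
    def supported(self) -> bool:
        return self.name in SUPPORTED_DATA_TYPES


@dataclass(frozen=True)
class CodeListDef:
    """Enumerated set of permitted coded values with decode labels."""

    oid: Oid
    name: str
    data_type: DataType
    options: Tuple[Tuple[str, str], ...]  # (coded value, decode label)

    def __post_init__(self) -> None:
        codes = [c for c, _ in self.options]
        if not codes:
            raise ModelError(f"code list {self.oid} has no options")
        if len(set(codes)) != len(codes):
            raise ModelError(f"code list {self.oid} has duplicate coded values")

    @property
    def codes(self) -> Tuple[str, ...]:
        return tuple(c for c, _ in self.options)

    def decode(self, code: str) -> Optional[str]:
        for c, d in self.options:
            if c == code:
                return d
        return None


@dataclass(frozen=True)
class ElementRef:
    """One placement of a definition under a parent, with its mandatory
    flag and document order."""

    target_oid: Oid
    mandatory: bool
    order: int = 0


@dataclass(frozen=True)
class ItemDef:
    oid: Oid
    name: str
    data_type: DataType
    question: Optional[str] = None
    codelist: Optional[CodeListDef] = None


@dataclass(frozen=True)
class ItemGroupDef:
    oid: Oid
    name: str
    repeating: bool
    refs: Tuple[ElementRef, ...] = ()


@dataclass(frozen=True)
class FormDef:
    oid: Oid
    name: str
    repeating: bool
    refs: Tuple[ElementRef, ...] = ()


@dataclass(frozen=True)
class StudyEventDef:
    oid: Oid
    name: str
    repeating: bool
    refs: Tuple[ElementRef, ...] = ()


DefT = Union[StudyEventDef, FormDef, ItemGroupDef, ItemDef]


@dataclass(frozen=True)
class PositionalElement:
    """One placement of a definition in the metadata tree.

    ``path`` runs from the study event down to this element and uniquely
    identifies it; the same definition may back multiple placements.
    """

    path: PathT
    level: str
    definition: DefT
    mandatory: bool
    children: Tuple["PositionalElement", ...] = ()

    @property
    def oid(self) -> Oid:
        return self.path[-1]

    @property
    def name(self) -> str:
        return self.definition.name

    def walk(self) -> Iterator["PositionalElement"]:
        yield self
        for child in self.children:
            yield from child.walk()


@dataclass
class DefinitionRegistry:
    """Per-class registries of definitions keyed by OID."""

    study_events: Mapping[Oid, StudyEventDef] = field(default_factory=dict)
    forms: Mapping[Oid, FormDef] = field(default_factory=dict)
    item_groups: Mapping[Oid, ItemGroupDef] = field(default_factory=dict)
    items: Mapping[Oid, ItemDef] = field(default_factory=dict)
    codelists: Mapping[Oid, CodeListDef] = field(default_factory=dict)


@dataclass
class MetadataTree:
    """Positional metadata hierarchy plus the definition registries."""

    study_oid: Oid
    study_name: str
    events: Tuple[PositionalElement, ...]
    registry: DefinitionRegistry
    _index: Mapping[PathT, PositionalElement] = field(default_factory=dict, repr=False)

    def elements(self) -> Iterator[PositionalElement]:
        """Pre-order traversal over every positional element."""
        for event in self.events:
            yield from event.walk()

    def lookup(self, path: Sequence[str]) -> Optional[PositionalElement]:
        return self._index.get(tuple(path))


@dataclass
class ElementInstance:
    """One occurrence of a positional element in a subject's data.

    ``repeat_keys`` accumulates the ``(level, key)`` discriminators seen on
    the way down; keys are opaque strings with no assumed ordering.  Items
    carry the raw value string (``None`` when the value was absent or
    empty) and, after semantic validation, a parsed payload.
    """

    path: PathT
    repeat_keys: RepeatKeysT = ()
    children: list = field(default_factory=list)
    value: Optional[str] = None
    typed: Optional[object] = None

    @property
    def level(self) -> str:
        return LEVELS[len(self.path) - 1]

    @property
    def oid(self) -> Oid:
        return self.path[-1]


@dataclass
class SubjectRecord:
    subject_key: str
    instances: list = field(default_factory=list)  # event-level ElementInstances


@dataclass
class ClinicalDataset:
    subjects: list = field(default_factory=list)

    @property
    def subject_count(self) -> int:
        return len(self.subjects)


# ---------------------------------------------------------------------------
# Tree construction


_CHILD_CLASS = {
    "study_event": ("forms", "form"),
    "form": ("item_groups", "item_group"),
    "item_group": ("items", "item"),
}


def _resolve(registry: DefinitionRegistry, level: str, oid: Oid) -> DefT:
    pool = {
        "study_event": registry.study_events,
        "form": registry.forms,
        "item_group": registry.item_groups,
        "item": registry.items,
    }[level]
    try:
        return pool[oid]
    except KeyError:
        raise MissingDefinitionError(f"no {level} definition for OID {oid!r}") from None


def _build_element(
    registry: DefinitionRegistry,
    level: str,
    path: PathT,
    mandatory: bool,
) -> PositionalElement:
    definition = _resolve(registry, level, path[-1])
    children: list = []
    if level != "item":
        _, child_level = _CHILD_CLASS[level]
        seen: set = set()
        for ref in definition.refs:
            if ref.target_oid in seen:
                raise StructuralModelError(
                    f"{child_level} {ref.target_oid!r} referenced twice under "
                    f"{level} {path[-1]!r}"
                )
            seen.add(ref.target_oid)
            children.append(
                _build_element(
                    registry, child_level, path + (ref.target_oid,), ref.mandatory
                )
            )
    return PositionalElement(
        path=path,
        level=level,
        definition=definition,
        mandatory=mandatory,
        children=tuple(children),
    )


def build_positional_tree(
    defs: DefinitionRegistry,
    study_refs: Sequence[ElementRef],
    study_oid: Oid,
    study_name: str = "",
) -> MetadataTree:
    """Expand definition registries into the positional hierarchy.

    Each placement of a definition becomes a separate
    :class:`PositionalElement`; within one parent each child OID may appear
    at most once.

    Raises
    ------
    MissingDefinitionError
        if a reference targets an OID with no definition.
    StructuralModelError
        if a child OID is referenced twice under the same parent.
    """
    events = []
    seen: set = set()
    for ref in study_refs:
        if ref.target_oid in seen:
            raise StructuralModelError(
                f"study event {ref.target_oid!r} referenced twice in the protocol"
            )
        seen.add(ref.target_oid)
        events.append(
            _build_element(defs, "study_event", (ref.target_oid,), ref.mandatory)
        )
    tree = MetadataTree(
        study_oid=study_oid,
        study_name=study_name,
        events=tuple(events),
        registry=defs,
    )
    index = {el.path: el for el in tree.elements()}
    tree._index = index
    return tree


def resolve_instance_path(
    tree: MetadataTree, instance: ElementInstance
) -> Optional[PositionalElement]:
    """Look up the positional element matching an instance path.

    Returns ``None`` when the path is not present in the tree; callers in
    the semantic-validation stage turn that into an undefined-reference
    finding rather than an exception.
    """
    return tree.lookup(instance.path)
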