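"""Recursive completeness measures over the cleaned dataset.

Two modes share one algorithm.  ``mandatory_flag`` honours the mandatory
flags carried by the references that placed each element; ``all_mandatory``
treats every element as mandatory, which is useful when flags were not
maintained but must be read with care for optional/conditional items.

An item instance is complete when it carries a non-empty value.  A
non-leaf instance is complete when every mandatory child element occurs at
least once inside it and every present child instance is itself complete;
applying the same rule over study events yields per-subject completeness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from .model import (
    ClinicalDataset,
    ElementInstance,
    MetadataTree,
    PathT,
    PositionalElement,
)

MANDATORY_FLAG = "mandatory_flag"
ALL_MANDATORY = "all_mandatory"
MODES = (MANDATORY_FLAG, ALL_MANDATORY)


@dataclass
class CompletenessNode:
    element: PositionalElement
    expected: int = 0
    completed: int = 0
    children: List["CompletenessNode"] = field(default_factory=list)

    @property
    def percentage(self) -> Optional[float]:
        """Percent complete; ``None`` (rendered n/a) when nothing was
        expected — a never-instantiated branch is not claimed complete."""
        if self.expected == 0:
            return None
        return 100.0 * self.completed / self.expected

    def walk(self):
        yield self
        for child in self.children:
            yield from child.walk()


@dataclass
class CompletenessReport:
    mode: str
    roots: List[CompletenessNode]
    completed_subjects: int
    total_subjects: int

    def node_at(self, path: PathT) -> Optional[CompletenessNode]:
        for root in self.roots:
            for node in root.walk():
                if node.element.path == tuple(path):
                    return node
        return None


def _is_mandatory(element: PositionalElement, mode: str) -> bool:
    return True if mode == ALL_MANDATORY else element.mandatory


def instance_complete(
    instance: ElementInstance, element: PositionalElement, mode: str
) -> bool:
    """Evaluate one instance against the recursive completeness rule."""
    if element.level == "item":
        return instance.value is not None
    children_by_oid: Dict[str, List[ElementInstance]] = {}
    for child in instance.children:
        children_by_oid.setdefault(child.oid, []).append(child)
    for child_el in element.children:
        present = children_by_oid.get(child_el.oid, [])
        if _is_mandatory(child_el, mode) and not present:
            return False
        for child_inst in present:
            if not instance_complete(child_inst, child_el, mode):
                return False
    return True


def _build_nodes(element: PositionalElement) -> CompletenessNode:
    return CompletenessNode(
        element=element, children=[_build_nodes(c) for c in element.children]
    )


def compute_completeness(
    tree: MetadataTree, clean: ClinicalDataset, mode: str
) -> CompletenessReport:
    """Per-element expected/completed counts plus subject-level totals.

    For element C with parent P::

        expected(C)  = #C instances present
                     + (C mandatory under mode ? #P instances without any C : 0)
        completed(C) = #complete C instances

    At subject level, expected is the subject total and completed counts
    subjects whose whole event forest satisfies the rule.
    """
    if mode not in MODES:
        raise ValueError(f"unknown completeness mode {mode!r}")
    roots = [_build_nodes(event) for event in tree.events]
    nodes_by_path: Dict[PathT, CompletenessNode] = {
        node.element.path: node for root in roots for node in root.walk()
    }

    def tally(element: PositionalElement, groups: List[List[ElementInstance]]) -> None:
        # ``groups`` holds, per parent instance, this element's instances
        # inside that parent; empty groups are parents missing the element.
        node = nodes_by_path[element.path]
        flat = [inst for group in groups for inst in group]
        expected = len(flat)
        if _is_mandatory(element, mode):
            expected += sum(1 for group in groups if not group)
        node.expected += expected
        node.completed += sum(
            1 for inst in flat if instance_complete(inst, element, mode)
        )
        for child_el in element.children:
            tally(
                child_el,
                [
                    [c for c in inst.children if c.oid == child_el.oid]
                    for inst in flat
                ],
            )

    completed_subjects = 0
    for subject in clean.subjects:
        events_by_oid: Dict[str, List[ElementInstance]] = {}
        for inst in subject.instances:
            events_by_oid.setdefault(inst.oid, []).append(inst)
        subject_ok = True
        for event_el in tree.events:
            present = events_by_oid.get(event_el.oid, [])
            if _is_mandatory(event_el, mode) and not present:
                subject_ok = False
            for inst in present:
                if not instance_complete(inst, event_el, mode):
                    subject_ok = False
        if subject_ok:
            completed_subjects += 1
        for event_el in tree.events:
            # the subject acts as the single parent of its event instances
            tally(event_el, [events_by_oid.get(event_el.oid, [])])
    return CompletenessReport(
        mode=mode,
        roots=roots,
        completed_subjects=completed_subjects,
        total_subjects=clean.subject_count,
    )


@dataclass(frozen=True)
class ModeDelta:
    path: PathT
    pct_flag: Optional[float]
    pct_all: Optional[float]


def compare_modes(
    report_flag: CompletenessReport, report_all: CompletenessReport
) -> List[ModeDelta]:
    """Elements whose completeness percentage drops under all-mandatory.

    Both reports must come from the same tree and dataset; the comparison
    relies on the monotonicity of the two modes (all-mandatory never
    expects less, never completes more).
    """
    deltas = []
    for root_f, root_a in zip(report_flag.roots, report_all.roots):
        for node_f, node_a in zip(root_f.walk(), root_a.walk()):
            pf, pa = node_f.percentage, node_a.percentage
            if pf is not None and pa is not None and pa < pf:
                deltas.append(ModeDelta(node_f.element.path, pf, pa))
    return deltas
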