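"""Scale-aware descriptive statistics for every positional element.

Items are grouped into five measurement-scale categories (after Stevens):
dichotomous (boolean), nominal (free text), ordinal (codelist-backed),
interval (time points) and ratio (numbers).  Every category gets its own
summary and chart kind; all values are used, including multiples arising
from repeat keys, and multi-contribution is flagged rather than averaged
away.
"""

from __future__ import annotations

import datetime as _dt
import statistics as _pystats
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .model import (
    ClinicalDataset,
    CodeListDef,
    ItemDef,
    MetadataTree,
    PathT,
    PositionalElement,
)
from .validation import InvalidValueRecord

DICHOTOMOUS = "dichotomous"
NOMINAL = "nominal"
ORDINAL = "ordinal"
INTERVAL = "interval"
RATIO = "ratio"

_CATEGORY_BY_TYPE = {
    "boolean": DICHOTOMOUS,
    "string": NOMINAL,
    "text": NOMINAL,
    "integer": RATIO,
    "float": RATIO,
    "double": RATIO,
    "date": INTERVAL,
    "time": INTERVAL,
    "datetime": INTERVAL,
}

DEFAULT_BINS = 10


class UnsupportedDataTypeError(Exception):
    """Raised by :func:`categorize` for data types outside the implemented
    set; callers skip the item and report it."""


@dataclass(frozen=True)
class CountSummary:
    reference_count: int
    subject_count: int


@dataclass(frozen=True)
class ChartData:
    """Rendering-independent chart content.

    ``kind`` is ``pie``, ``bar`` or ``histogram``.  Pie/bar charts carry
    labels (and, for ordinal bars, decode labels) with counts; histograms
    carry strictly increasing bucket borders as doubles.
    """

    kind: str
    labels: Tuple[str, ...] = ()
    decodes: Tuple[str, ...] = ()
    counts: Tuple[int, ...] = ()
    borders: Tuple[float, ...] = ()

    @property
    def total(self) -> int:
        return int(sum(self.counts))


@dataclass(frozen=True)
class TopList:
    """Top-three exact-match value counts plus the observed diversity."""

    entries: Tuple[Tuple[str, int], ...]
    diversity: int
    diversity_total: Optional[int] = None  # codelist size, ordinal only


@dataclass(frozen=True)
class DichotomousSummary:
    true_count: int
    false_count: int

    @property
    def n(self) -> int:
        return self.true_count + self.false_count


@dataclass(frozen=True)
class IntervalSummary:
    minimum: object  # date / time / datetime
    maximum: object
    n: int


@dataclass(frozen=True)
class RatioSummary:
    minimum: float
    maximum: float
    mean: float
    median: float
    stddev: float
    n: int


@dataclass(frozen=True)
class ItemStatistics:
    element: PositionalElement
    counts: CountSummary
    category: str
    summary: object  # category-specific record, None when no data
    chart: Optional[ChartData]
    repeat_key_warning: bool
    invalid_value_warning: bool


def categorize(item: ItemDef) -> str:
    """Map an item definition onto its measurement-scale category.

    Codelist presence wins over the base data type (all codelist-backed
    items are ordinal, whatever the list's type).
    """
    if item.codelist is not None:
        return ORDINAL
    try:
        return _CATEGORY_BY_TYPE[item.data_type.name]
    except KeyError:
        raise UnsupportedDataTypeError(item.data_type.name) from None


# ---------------------------------------------------------------------------
# Instance gathering


def _gather(clean: ClinicalDataset) -> Dict[PathT, List[Tuple[str, object]]]:
    """Map each positional path to its [(subject_key, instance)] list."""
    out: Dict[PathT, List[Tuple[str, object]]] = {}

    def visit(subject_key, instance):
        out.setdefault(instance.path, []).append((subject_key, instance))
        for child in instance.children:
            visit(subject_key, child)

    for subject in clean.subjects:
        for instance in subject.instances:
            visit(subject.subject_key, instance)
    return out


def count_references(
    element: PositionalElement, clean: ClinicalDataset
) -> CountSummary:
    """Reference/subject counts for one positional element.

    The reference count tallies every instance across subjects and repeat
    keys, so it may exceed the subject count.
    """
    gathered = _gather(clean).get(element.path, [])
    return CountSummary(
        reference_count=len(gathered),
        subject_count=len({s for s, _ in gathered}),
    )


def flag_repeat_keys(element: PositionalElement, clean: ClinicalDataset) -> bool:
    """True iff any subject contributes more than one instance here."""
    per_subject = Counter(s for s, _ in _gather(clean).get(element.path, []))
    return any(c > 1 for c in per_subject.values())


# ---------------------------------------------------------------------------
# Category statistics


def stats_dichotomous(values: Sequence[bool]) -> Tuple[DichotomousSummary, Optional[ChartData]]:
    true_count = sum(1 for v in values if v)
    summary = DichotomousSummary(true_count, len(values) - true_count)
    if not values:
        return summary, None
    chart = ChartData(
        kind="pie",
        labels=("True", "False"),
        counts=(summary.true_count, summary.false_count),
    )
    return summary, chart


def _top_entries(counter: Counter, k: int = 3) -> Tuple[Tuple[str, int], ...]:
    # count descending, then value ascending by code point, for determinism
    ranked = sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
    return tuple(ranked[:k])


def stats_nominal(values: Sequence[str]) -> TopList:
    """Top-three exact (byte-equal) string matches; no chart for free text."""
    counter = Counter(values)
    return TopList(entries=_top_entries(counter), diversity=len(counter))


def stats_ordinal(
    values: Sequence[str], codelist: CodeListDef
) -> Tuple[TopList, Optional[ChartData]]:
    """Per-option counts for a codelist-backed item.

    The bar chart shows at most ten options: with ten or fewer in the list,
    all of them; otherwise the top nine by count plus one "others" bar
    summing the rest.
    """
    counter = Counter(values)
    top = TopList(
        entries=_top_entries(counter),
        diversity=len(counter),
        diversity_total=len(codelist.codes),
    )
    if not values:
        return top, None
    option_counts = [(code, counter.get(code, 0)) for code in codelist.codes]
    decode_by_code = dict(codelist.options)
    if len(option_counts) <= 10:
        chosen = option_counts
        others = None
    else:
        ranked = sorted(option_counts, key=lambda kv: (-kv[1], kv[0]))
        chosen = ranked[:9]
        others = sum(c for _, c in ranked[9:])
    labels = [code for code, _ in chosen]
    decodes = [decode_by_code.get(code, code) for code, _ in chosen]
    counts = [c for _, c in chosen]
    if others is not None:
        labels.append("others")
        decodes.append("others")
        counts.append(others)
    return top, ChartData(
        kind="bar", labels=tuple(labels), decodes=tuple(decodes),
        counts=tuple(counts),
    )


def _encode_timepoint(value: object) -> float:
    """Numeric encoding for histogram binning of time points."""
    if isinstance(value, _dt.datetime):
        return value.replace(tzinfo=_dt.timezone.utc).timestamp()
    if isinstance(value, _dt.date):
        return float((value - _dt.date(1970, 1, 1)).days)
    if isinstance(value, _dt.time):
        return value.hour * 3600 + value.minute * 60 + value.second + value.microsecond / 1e6
    raise TypeError(type(value))


def stats_interval(
    values: Sequence[object], n_bins: int = DEFAULT_BINS
) -> Tuple[Optional[IntervalSummary], Optional[ChartData]]:
    """Chronological range plus a histogram over a numeric encoding.

    Deliberately no mean: averages of visit dates carry no insight.  With
    no data, both results are ``None``.
    """
    if not values:
        return None, None
    summary = IntervalSummary(minimum=min(values), maximum=max(values), n=len(values))
    encoded = [_encode_timepoint(v) for v in values]
    return summary, make_histogram(encoded, n_bins)


def stats_ratio(
    values: Sequence[float], n_bins: int = DEFAULT_BINS
) -> Tuple[Optional[RatioSummary], Optional[ChartData]]:
    """Min/max/mean/median/sample-stddev over doubles, plus a histogram.

    Median of an even-sized sample is the mean of the two central order
    statistics; the standard deviation uses the n−1 denominator, with the
    n=1 case fixed at 0 by convention.
    """
    if not values:
        return None, None
    values = [float(v) for v in values]
    summary = RatioSummary(
        minimum=min(values),
        maximum=max(values),
        mean=_pystats.fmean(values),
        median=float(_pystats.median(values)),
        stddev=_pystats.stdev(values) if len(values) > 1 else 0.0,
        n=len(values),
    )
    return summary, make_histogram(values, n_bins)


def make_histogram(values: Sequence[float], n_bins: int = DEFAULT_BINS) -> ChartData:
    """Equal-width histogram spanning [min, max].

    The rightmost bin is closed on both sides; a degenerate range (all
    values identical) collapses to a single bin holding everything.
    Borders are reported as doubles even for integer-valued input.
    """
    if not values:
        raise ValueError("make_histogram requires at least one value")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    lo, hi = float(min(values)), float(max(values))
    if lo == hi:
        return ChartData(
            kind="histogram", counts=(len(values),), borders=(lo - 0.5, hi + 0.5)
        )
    counts, borders = np.histogram(
        np.asarray(values, dtype=float), bins=n_bins, range=(lo, hi)
    )
    return ChartData(
        kind="histogram",
        counts=tuple(int(c) for c in counts),
        borders=tuple(float(b) for b in borders),
    )


# ---------------------------------------------------------------------------
# Whole-dataset analysis


@dataclass
class AnalysisOutcome:
    element_counts: Dict[PathT, CountSummary]
    repeat_flags: Dict[PathT, bool]
    invalid_flags: Dict[PathT, bool]
    items: List[ItemStatistics]
    skipped_items: List[Tuple[PathT, str]] = field(default_factory=list)


def _item_values(instances: List[Tuple[str, object]]) -> list:
    return [
        (s, inst.typed) for s, inst in instances
        if inst.value is not None and inst.typed is not None
    ]


def analyze(
    tree: MetadataTree,
    clean: ClinicalDataset,
    invalid: Sequence[InvalidValueRecord] = (),
    n_bins: int = DEFAULT_BINS,
) -> AnalysisOutcome:
    """Compute counts for every positional element and statistics per item.

    Works on the cleaned dataset; elements touched by invalid records keep
    a warning flag so the exclusions stay visible.  Items whose data type
    has no implemented statistic are skipped and listed separately.
    """
    gathered = _gather(clean)
    invalid_paths = {rec.path for rec in invalid}

    def has_invalid_below(path: PathT) -> bool:
        return any(p[: len(path)] == path for p in invalid_paths)

    element_counts: Dict[PathT, CountSummary] = {}
    repeat_flags: Dict[PathT, bool] = {}
    invalid_flags: Dict[PathT, bool] = {}
    items: List[ItemStatistics] = []
    skipped: List[Tuple[PathT, str]] = []

    for element in tree.elements():
        instances = gathered.get(element.path, [])
        counts = CountSummary(
            reference_count=len(instances),
            subject_count=len({s for s, _ in instances}),
        )
        per_subject = Counter(s for s, _ in instances)
        repeat = any(c > 1 for c in per_subject.values())
        element_counts[element.path] = counts
        repeat_flags[element.path] = repeat
        invalid_flags[element.path] = has_invalid_below(element.path)
        if element.level != "item":
            continue
        item_def: ItemDef = element.definition
        try:
            category = categorize(item_def)
        except UnsupportedDataTypeError:
            skipped.append((element.path, item_def.data_type.name))
            continue
        typed = [tv for _, tv in _item_values(instances)]
        summary: object
        chart: Optional[ChartData]
        if category == DICHOTOMOUS:
            summary, chart = stats_dichotomous([tv.payload for tv in typed])
            if summary.n == 0:
                summary = None
        elif category == NOMINAL:
            summary = stats_nominal([tv.payload for tv in typed]) if typed else None
            chart = None
        elif category == ORDINAL:
            summary, chart = stats_ordinal(
                [tv.payload for tv in typed], item_def.codelist
            )
            if not typed:
                summary = None
        elif category == INTERVAL:
            summary, chart = stats_interval([tv.payload for tv in typed], n_bins)
        else:
            summary, chart = stats_ratio([tv.payload for tv in typed], n_bins)
        items.append(
            ItemStatistics(
                element=element,
                counts=counts,
                category=category,
                summary=summary,
                chart=chart,
                repeat_key_warning=repeat,
                invalid_value_warning=invalid_flags[element.path],
            )
        )
    return AnalysisOutcome(
        element_counts=element_counts,
        repeat_flags=repeat_flags,
        invalid_flags=invalid_flags,
        items=items,
        skipped_items=skipped,
    )


# ---------------------------------------------------------------------------
# Rendering of summary strings


def _fmt_timepoint(value: object) -> str:
    if isinstance(value, _dt.datetime):
        return value.strftime("%H:%M:%S on %d %B %Y")
    if isinstance(value, _dt.date):
        return value.strftime("%d %B %Y")
    return value.strftime("%H:%M:%S")


def _fmt_top(entries: Tuple[Tuple[str, int], ...]) -> str:
    return " | ".join(f"{i}. {v} ({c})" for i, (v, c) in enumerate(entries, 1))


def format_summary(stat: ItemStatistics) -> str:
    """One-line statistical output per item, shaped per category:

    * dichotomous — ``True: 55 - False: 45``
    * nominal — ``Diversity: 22 - Top3: 1. red (9) | 2. green (7) | 3. blue (5)``
    * ordinal — ``Diversity: 3/3 - Top3: 1. Yes (8) | 2. No (4) | 3. Maybe (3)``
    * interval — ``Range: 13:54:47 on 05 May 1920 - 20:11:59 on 09 June 2010``
    * ratio — ``Min: 1.1 | Max: 8.8 | Mean: 4.9 | Median: 4.4 | StdDev: 2.6``
    """
    s = stat.summary
    if s is None:
        return "No data"
    if stat.category == DICHOTOMOUS:
        return f"True: {s.true_count} - False: {s.false_count}"
    if stat.category == NOMINAL:
        return f"Diversity: {s.diversity} - Top3: {_fmt_top(s.entries)}"
    if stat.category == ORDINAL:
        return (
            f"Diversity: {s.diversity}/{s.diversity_total} - "
            f"Top3: {_fmt_top(s.entries)}"
        )
    if stat.category == INTERVAL:
        return f"Range: {_fmt_timepoint(s.minimum)} - {_fmt_timepoint(s.maximum)}"
    return (
        f"Min: {s.minimum:.1f} | Max: {s.maximum:.1f} | Mean: {s.mean:.1f} | "
        f"Median: {s.median:.1f} | StdDev: {s.stddev:.1f}"
    )
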