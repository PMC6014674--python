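"""Report assembly: structured JSON output, paginated document, charts.

:func:`run_analysis` orchestrates the whole pipeline (parse → validate →
statistics / completeness) and returns an :class:`AnalysisReport`.  The
report serializes to a stable JSON document; an optional paginated
rendering (PDF via matplotlib when available, single-file HTML otherwise)
devotes one section per item, mirroring the on-screen analysis with the
category summary string, chart data and warning markers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

from . import __version__
from .completeness import (
    ALL_MANDATORY,
    MANDATORY_FLAG,
    CompletenessNode,
    CompletenessReport,
    compute_completeness,
)
from .reader import ParseResult, parse_odm
from .stats import (
    AnalysisOutcome,
    ChartData,
    ItemStatistics,
    analyze,
    format_summary,
)
from .validation import InvalidValueRecord, export_invalid_csv, validate_dataset

TOOL_NAME = "odm-insight"


@dataclass
class AnalysisOptions:
    statistics: bool = True
    completeness: bool = False
    completeness_modes: Sequence[str] = (MANDATORY_FLAG,)
    n_bins: int = 10


@dataclass
class AnalysisReport:
    study_oid: str
    study_name: str
    odm_version: Optional[str]
    options: AnalysisOptions
    structural_errors: List = field(default_factory=list)
    warnings: List[str] = field(default_factory=list)
    outcome: Optional[AnalysisOutcome] = None
    completeness: Dict[str, CompletenessReport] = field(default_factory=dict)
    invalid: List[InvalidValueRecord] = field(default_factory=list)

    @property
    def aborted(self) -> bool:
        return bool(self.structural_errors)


def run_analysis(source, options: Optional[AnalysisOptions] = None) -> AnalysisReport:
    """Run the full pipeline over one ODM document.

    Structural failure aborts with the error list in the report; semantic
    findings (invalid values) never abort.
    """
    options = options or AnalysisOptions()
    parsed: ParseResult = parse_odm(source)
    if not parsed.ok:
        return AnalysisReport(
            study_oid="", study_name="", odm_version=parsed.version,
            options=options,
            structural_errors=list(parsed.structural_errors),
        )
    tree = parsed.metadata
    clean, invalid = validate_dataset(tree, parsed.clinical)
    report = AnalysisReport(
        study_oid=str(tree.study_oid),
        study_name=tree.study_name,
        odm_version=parsed.version,
        options=options,
        warnings=list(parsed.warnings),
        invalid=invalid,
    )
    if options.statistics:
        report.outcome = analyze(tree, clean, invalid, n_bins=options.n_bins)
    if options.completeness:
        for mode in options.completeness_modes:
            report.completeness[mode] = compute_completeness(tree, clean, mode)
    return report


# ---------------------------------------------------------------------------
# JSON serialization


def _chart_dict(chart: Optional[ChartData]) -> Optional[dict]:
    if chart is None:
        return None
    out = {"kind": chart.kind, "counts": list(chart.counts)}
    if chart.labels:
        out["labels"] = list(chart.labels)
    if chart.decodes:
        out["decodes"] = list(chart.decodes)
    if chart.borders:
        out["borders"] = list(chart.borders)
    return out


def _summary_dict(stat: ItemStatistics) -> Optional[dict]:
    s = stat.summary
    if s is None:
        return None
    if stat.category == "dichotomous":
        return {"true": s.true_count, "false": s.false_count}
    if stat.category in ("nominal", "ordinal"):
        out = {"top": [[v, c] for v, c in s.entries], "diversity": s.diversity}
        if s.diversity_total is not None:
            out["diversity_total"] = s.diversity_total
        return out
    if stat.category == "interval":
        return {"min": s.minimum.isoformat(), "max": s.maximum.isoformat(),
                "n": s.n}
    return {"min": s.minimum, "max": s.maximum, "mean": s.mean,
            "median": s.median, "stddev": s.stddev, "n": s.n}


def _item_dict(stat: ItemStatistics) -> dict:
    return {
        "path": list(stat.element.path),
        "name": stat.element.name,
        "category": stat.category,
        "reference_count": stat.counts.reference_count,
        "subject_count": stat.counts.subject_count,
        "summary": _summary_dict(stat),
        "summary_text": format_summary(stat),
        "chart": _chart_dict(stat.chart),
        "repeat_key_warning": stat.repeat_key_warning,
        "invalid_value_warning": stat.invalid_value_warning,
    }


def _completeness_node_dict(node: CompletenessNode) -> dict:
    return {
        "path": list(node.element.path),
        "level": node.element.level,
        "expected": node.expected,
        "completed": node.completed,
        "percentage": node.percentage,
        "children": [_completeness_node_dict(c) for c in node.children],
    }


def _invalid_dict(rec: InvalidValueRecord) -> dict:
    return {
        "subject_key": rec.subject_key,
        "path": list(rec.path),
        "repeat_keys": [[level, key] for level, key in rec.repeat_keys],
        "raw_value": rec.raw_value,
        "reason": rec.reason.code,
        "detail": rec.reason.detail,
    }


def report_to_dict(report: AnalysisReport) -> dict:
    out: dict = {
        "tool": {"name": TOOL_NAME, "version": __version__},
        "study": {"oid": report.study_oid, "name": report.study_name,
                  "odm_version": report.odm_version},
        "options": {
            "statistics": report.options.statistics,
            "completeness": report.options.completeness,
            "completeness_modes": list(report.options.completeness_modes),
            "n_bins": report.options.n_bins,
        },
        "warnings": list(report.warnings),
    }
    if report.structural_errors:
        out["structural_errors"] = [
            {"line": e.line, "xml_path": e.xml_path, "message": e.message}
            for e in report.structural_errors
        ]
        return out
    if report.outcome is not None:
        out["elements"] = [
            {"path": list(path),
             "reference_count": cs.reference_count,
             "subject_count": cs.subject_count,
             "repeat_key_warning": report.outcome.repeat_flags[path],
             "invalid_value_warning": report.outcome.invalid_flags[path]}
            for path, cs in report.outcome.element_counts.items()
        ]
        out["items"] = [_item_dict(stat) for stat in report.outcome.items]
        if report.outcome.skipped_items:
            out["skipped_items"] = [
                {"path": list(path), "data_type": dtype}
                for path, dtype in report.outcome.skipped_items
            ]
    if report.completeness:
        out["completeness"] = {
            mode: {
                "completed_subjects": rep.completed_subjects,
                "total_subjects": rep.total_subjects,
                "roots": [_completeness_node_dict(r) for r in rep.roots],
            }
            for mode, rep in report.completeness.items()
        }
    if report.invalid:
        out["invalid_values"] = [_invalid_dict(r) for r in report.invalid]
    return out


def serialize_report(report, sink) -> None:
    """Write the report as canonical JSON (UTF-8, sorted keys).

    Accepts an :class:`AnalysisReport` or an already-built dict, so a
    read → write round trip is byte-identical.
    """
    data = report if isinstance(report, dict) else report_to_dict(report)
    text = json.dumps(data, indent=2, sort_keys=True, ensure_ascii=False) + "\n"
    if isinstance(sink, (str, bytes)):
        with open(sink, "w", encoding="utf-8") as fh:
            fh.write(text)
    else:
        sink.write(text)


def load_report(path: str) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# Paginated document


def _warn_markers(stat: ItemStatistics) -> str:
    marks = []
    if stat.repeat_key_warning:
        marks.append("[repeat keys]")
    if stat.invalid_value_warning:
        marks.append("[invalid values]")
    return " ".join(marks)


def _chart_table_html(chart: Optional[ChartData]) -> str:
    if chart is None:
        return "<p class='nochart'>No chart for this category.</p>"
    if chart.kind == "histogram":
        rows = "".join(
            f"<tr><td>[{chart.borders[i]:g}, {chart.borders[i + 1]:g}"
            f"{']' if i == len(chart.counts) - 1 else ')'}</td>"
            f"<td>{c}</td></tr>"
            for i, c in enumerate(chart.counts)
        )
        header = "<tr><th>bucket</th><th>count</th></tr>"
    else:
        rows = "".join(
            f"<tr><td>{label}</td><td>{count}</td></tr>"
            for label, count in zip(chart.labels, chart.counts)
        )
        header = "<tr><th>option</th><th>count</th></tr>"
    return f"<table class='chart {chart.kind}'>{header}{rows}</table>"


def render_document(report: AnalysisReport, path: str) -> int:
    """Render the paginated per-item document; returns the section count.

    A ``.pdf`` suffix selects the matplotlib renderer (one page per item,
    with the actual chart drawn); any other suffix produces a single-file
    HTML document with identical content.
    """
    if report.outcome is None:
        raise ValueError("document rendering requires the statistics section")
    items = report.outcome.items
    if path.lower().endswith(".pdf"):
        _render_pdf(report, items, path)
    else:
        _render_html(report, items, path)
    return len(items)


def _render_html(report: AnalysisReport, items: List[ItemStatistics],
                 path: str) -> None:
    parts = [
        "<!DOCTYPE html><html><head><meta charset='utf-8'>",
        f"<title>{report.study_name or report.study_oid}</title>",
        "<style>body{font-family:sans-serif}section{page-break-after:always;"
        "border-bottom:1px solid #ccc;margin-bottom:1em}"
        "table.chart td,table.chart th{border:1px solid #999;padding:2px 6px}"
        "</style></head><body>",
        f"<h1>Analysis report — {report.study_name or report.study_oid}</h1>",
        f"<p>Study OID: {report.study_oid} | ODM version: "
        f"{report.odm_version} | {TOOL_NAME} {__version__}</p>",
    ]
    for stat in items:
        parts.append("<section class='item'>")
        parts.append(f"<h2>{stat.element.name} ({'/'.join(stat.element.path)})</h2>")
        parts.append(
            f"<p>Category: {stat.category} | References: "
            f"{stat.counts.reference_count} | Subjects: "
            f"{stat.counts.subject_count} {_warn_markers(stat)}</p>"
        )
        parts.append(f"<p class='summary'>{format_summary(stat)}</p>")
        parts.append(_chart_table_html(stat.chart))
        parts.append("</section>")
    parts.append("</body></html>")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(parts))


def _render_pdf(report: AnalysisReport, items: List[ItemStatistics],
                path: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.backends.backend_pdf import PdfPages

    with PdfPages(path) as pdf:
        if not items:
            fig = plt.figure(figsize=(8.27, 11.69))
            fig.text(0.5, 0.6, report.study_name or report.study_oid,
                     ha="center", fontsize=16)
            fig.text(0.5, 0.5, "No items analyzed", ha="center")
            pdf.savefig(fig)
            plt.close(fig)
            return
        for stat in items:
            fig = plt.figure(figsize=(8.27, 11.69))
            fig.suptitle(f"{stat.element.name} ({'/'.join(stat.element.path)})")
            fig.text(0.1, 0.9, f"Category: {stat.category} | References: "
                               f"{stat.counts.reference_count} | Subjects: "
                               f"{stat.counts.subject_count}")
            fig.text(0.1, 0.87, format_summary(stat), fontsize=9)
            marks = _warn_markers(stat)
            if marks:
                fig.text(0.1, 0.84, marks, color="darkred")
            if stat.chart is not None:
                ax = fig.add_axes([0.15, 0.2, 0.7, 0.55])
                _draw_chart(ax, stat.chart)
            pdf.savefig(fig)
            plt.close(fig)


def _draw_chart(ax, chart: ChartData) -> None:
    if chart.kind == "pie":
        shown = [(l, c) for l, c in zip(chart.labels, chart.counts) if c > 0]
        if shown:
            ax.pie([c for _, c in shown],
                   labels=[f"{l} ({c})" for l, c in shown])
    elif chart.kind == "bar":
        ax.bar(range(len(chart.counts)), chart.counts)
        ax.set_xticks(range(len(chart.counts)))
        ax.set_xticklabels(chart.labels, rotation=45, ha="right", fontsize=7)
    else:
        widths = [chart.borders[i + 1] - chart.borders[i]
                  for i in range(len(chart.counts))]
        ax.bar(chart.borders[:-1], chart.counts, width=widths, align="edge",
               edgecolor="white")


def render_charts(report: AnalysisReport, directory: str) -> List[str]:
    """Write one PNG per item chart, named by positional path."""
    import os

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if report.outcome is None:
        raise ValueError("chart rendering requires the statistics section")
    os.makedirs(directory, exist_ok=True)
    written = []
    for stat in report.outcome.items:
        if stat.chart is None:
            continue
        fig, ax = plt.subplots(figsize=(6, 4))
        _draw_chart(ax, stat.chart)
        ax.set_title(stat.element.name, fontsize=9)
        name = "_".join(stat.element.path) + ".png"
        target = os.path.join(directory, name)
        fig.savefig(target, dpi=100)
        plt.close(fig)
        written.append(target)
    return written


def export_invalid(report: AnalysisReport, sink) -> int:
    return export_invalid_csv(report.invalid, sink)
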