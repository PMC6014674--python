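# odm-insight

Validation, completeness measures and scale-aware descriptive statistics
for CDISC ODM 1.3.x study exports (`ODM 1.3.0 / 1.3.1 / 1.3.2`).

Given a single ODM XML file carrying one study's metadata and clinical
data, the tool

1. **validates the structure** against an explicit grammar for the
   supported ODM element subset (required attributes, nesting order,
   attribute lexical forms, no foreign-namespace extensions) — structural
   failure aborts the analysis with a list of located errors;
2. **validates the content**: every clinical path must resolve into the
   *positional* metadata tree, every item value must convert into its
   declared data type, codelist-backed values must be list members.
   Findings become invalid-value records (exportable as CSV) and the
   offending entries are excluded from further analysis;
3. **computes descriptive statistics** per positional element
   (reference/subject counts) and per item, grouped into five
   measurement-scale categories: dichotomous (boolean → true/false counts,
   pie chart), nominal (free text → top-3 exact-match strings), ordinal
   (codelist → per-option counts, bar chart with at most ten bars, the
   tenth summarizing "others"), interval (time points → range + histogram)
   and ratio (numbers → min/max/mean/median/sample SD + histogram).
   All values are used, including repeat-key multiples; multi-contribution
   is flagged, never averaged away;
4. **computes two completeness measures** recursively from items up to
   subjects — one honouring the mandatory flags on the placing references,
   one treating every element as mandatory.

A definition referenced from two places is analyzed as two distinct
positional elements (a form shared by two study events yields two
independent statistics blocks).

Because no public study exports exist, the package ships a first-class
fixture generator (`odm_insight.fixtures`) that emits deterministic ODM
1.3.2 files with controllable structure, repeat keys, missingness,
injected semantic errors and structural faults, together with an
independently computed ground-truth manifest.

## CLI

```sh
odm-insight INPUT.xml [--statistics] [--completeness]
            [--completeness-mode mandatory|all|both]
            [--report-json OUT.json] [--invalid-csv OUT.csv]
            [--report-doc OUT.pdf|OUT.html] [--bins N]
            [--charts DIR] [--log-level LEVEL]
```

Exit codes: `0` success, `2` structural-validation failure, `1` usage or
I/O error. `--report-doc` renders one section/page per item and requires
`--statistics`; a `.pdf` suffix selects the matplotlib renderer, anything
else produces single-file HTML with identical content. The JSON report is
deterministic (same input + options → byte-identical output) and captures
every computed number at full precision.

## Library

```python
from odm_insight.reader import parse_odm
from odm_insight.validation import validate_dataset
from odm_insight.stats import analyze
from odm_insight.completeness import compute_completeness

parsed = parse_odm("study.xml")         # structural gate + streaming parse
clean, invalid = validate_dataset(parsed.metadata, parsed.clinical)
outcome = analyze(parsed.metadata, clean, invalid)
report = compute_completeness(parsed.metadata, clean, "mandatory_flag")
```

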