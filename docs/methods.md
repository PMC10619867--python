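# Methods

This note documents the statistical conventions, configuration surface, and
synthetic-data design behind `aquaqc`, and what the test suite does and does
not establish.

## Input model

All inputs are string tables (CSV or XLSX) in five fixed templates: results,
DQO accuracy, DQO frequency & completeness, site metadata, and WQX metadata.
Cells are held verbatim as strings — including the censoring tokens `BDL`
(below detection limit) and `AQL` (above quantification limit) — so that a
write/read cycle round-trips every cell bit-exact; numbers are parsed only
at the point of use. Dates are normalized once, on successful validation,
to `YYYY-MM-DD` (accepted input forms: ISO dates and timestamps, `M/D/YYYY`,
and spreadsheet serial day numbers); normalization is idempotent.

The results validator runs fifteen named checks in a fixed order and aborts
at the first failure with the offending values and 1-based data-row indices
(header excluded; a config switch adds +1 for spreadsheet-style addresses).
Two conditions warn instead of failing — sample depths greater than
1 m / 3.3 ft, and missing sample times — because both can be legitimate;
`strict=True` promotes warnings to failures. Controlled vocabularies
(activity types, relative depth names, depth units), the parameter
dictionary (allowed units, one reporting unit per parameter), and the
parameters permitted to be negative (default: water temperature) all live in
an editable YAML-backed configuration rather than code.

## Criterion grammar

A DQO accuracy cell is one of: a comparison `<op> <number>[%]` with
`op ∈ {<, <=, >, >=}` (the `%` suffix marks a criterion on a percent
statistic), a bare `BDL`/`AQL` (the QC sample must itself be censored), the
token `log` (no criterion; marks the parameter as log-distributed), or
empty (no check of that type). A rule may be restricted to a value range;
when ranges overlap, the narrowest applicable range wins, ties broken by
file order.

## QC evaluation conventions

* **Blanks**: a censored reading is a hit; a numeric reading is a hit iff it
  satisfies the criterion. Under a strict `<` threshold, a reading equal to
  the threshold is a miss ("at or above the threshold").
* **Duplicates**: the precision statistic for percent criteria is the
  relative percent difference, `RPD = 100·|v−r|/mean(v,r)`, the standard
  QA/QC convention for duplicate precision; absolute criteria compare
  `|v−r|`. A pair with both members censored is a hit (indistinguishable);
  a mixed pair substitutes MDL/2 or the UQL for the censored member and logs
  the substitution; a zero pair mean under a percent criterion falls back to
  an exact-equality test. Field-duplicate pairs are stored in one row, the
  second member in the *QC Reference Value* column; lab duplicates use their
  own activity type with the pair in the same column.
* **Spikes / instrument checks**: percent criteria compare
  `100·|v−r|/r` against the known quantity `r` (equivalently
  `|100 − percent recovery|`); `r = 0` under a percent criterion excludes
  the record with a notice. Field calibration checks are folded into the
  same five-column report layout as lab spikes.
* **Acceptance percent**: `round(100·(n − misses)/n)` to the nearest
  integer, halves away from zero (the rule consistent with the displayed
  values 90.909→91 and 85.714→86 and deterministic at .5 ties); `-` marks
  cells with no QC records.
* **Frequency**: per parameter and check type,
  `100·n_qc / n_regular ≥ required`, where the denominator counts that
  parameter's regular (non-QC) records *excluding* qualified samples — a
  qualified sample is already serving as a QC carrier, so counting it as a
  plain regular observation would double-count it. Same-row duplicate pairs
  count as one check.
* **Completeness**: `100·(n_records − n_qualified)/n_records ≥ required`,
  with qualified records defined as regular rows carrying a paired QC value
  plus any rows flagged by a configurable qualifier column.

Every QC record yields exactly one verdict or one logged exclusion notice;
nothing is silently dropped.

## Outlier screening

Within each group (month, week, year, or station), observations outside
`[Q1 − 1.5·IQR, Q3 + 1.5·IQR]` are flagged. Quartiles use linear
interpolation between order statistics (the common type-7 estimator; the
test oracle implements the same rule independently). Only regular
monitoring records are screened: QC rows are excluded because a blank
(`BDL` → MDL/2) would otherwise always flag low and blanks carry no station
label. Parameters whose accuracy DQOs carry a `log` token are screened on
log10 of the substituted values, so a value extreme on the raw scale but
ordinary on the log scale is not flagged; non-positive values are excluded
from log screening with a notice. Groups with fewer than four points are
skipped — quartiles are too unstable there to call outliers. Flagging is
reporting only; the decision of what to do with an outlier stays with the
user.

A note on a tempting invariant that is *false* for interpolated quartiles:
inserting a duplicate of the median can tighten the quartile interval and
newly flag borderline points (e.g. in `[1, 4, 5, 6, 9]`, adding 5 moves the
bounds from [1, 9] to [2, 8] and flags 1 and 9). The sound direction —
inserting the median never *removes* existing flags — is what the property
suite asserts.

## Summaries and confidence intervals

`auto` settings resolve from the accuracy DQOs: log-hinted parameters get a
log10 axis and the geometric mean, others a linear axis and the arithmetic
mean; explicit choices (mean, geomean, median, min, max) override. Censored
values feed every summary through the same MDL/2 / UQL substitution as
outlier screening so all views agree. Date aggregates optionally carry 95%
normal-theory intervals `stat ± 1.96·SE` for groups with n ≥ 2; for
geometric means the interval is computed on log10 values and
back-transformed, giving an asymmetric interval whose coverage is exact only
under log-normality — a deliberate, conventional approximation. Threshold
overlays (editable per-parameter fresh/marine reference values with a
source string shown in the legend) are pure presentation and never enter the
statistics. Spatial aggregation joins per-site statistics to coordinates;
map rendering is a simple scatter hook accepting user-supplied line layers —
hydrography retrieval and base-map tiles are out of scope.

## WQX workbook

The submission workbook has exactly the sheets `Project`, `Locations`, and
`Results`, with the Results column set following the USEPA physical/chemical
template and kept in configuration so template revisions need no code
change. Censored results export a blank value plus detection-condition text
(`Not Detected` / `Present Above Quantification Limit`) and the MDL/UQL from
the accuracy DQOs — never a fabricated number. Same-row duplicate pairs
expand into two rows with paired activity types (e.g. `Quality Control
Sample-Lab Duplicate 1`/`2`); the expansion factor is logged. Time zone and
sample-collection defaults are configuration values. All cells are written
as text so the workbook round-trips exactly.

## Synthetic-data design

The generator produces a full five-table bundle as a deterministic function
of `(spec, seed)`: six stations, biweekly sampling May–September (eleven
events, 66 regular records per parameter), eight parameters — four field
measurements (DO, water temperature, pH, specific conductance) and four lab
concentrations (ammonia, TP, nitrate, E. coli), with E. coli log-flagged —
each with plausible centers, units, detection limits, and DQO criteria.
QC activities are interleaved at one per lab check type per event
(~19% frequency) and field-duplicate pairs at a 12% rate, against required
DQOs of 10% frequency and 85% completeness. Three percent of each lab
parameter's lowest regular values are censored to `BDL`.

Injected anomalies are the ground truth for recovery tests: two extreme DO
values (3× the bulk upper bound, one in the first and one in the last month)
and three QC misses (an ammonia field-duplicate pair, an ammonia lab blank,
a TP field blank at its threshold), all recorded in a JSON sidecar. Regular
values are drawn from narrow uniform bulks (uniform on log10 for log
parameters); because interpolated-quartile whiskers can still flag points of
a finite uniform sample, the generator additionally *guarantees* its ground
truth by construction: after injection it pulls any naturally flagged bulk
point of an injected parameter to its group median (injected rows held
fixed), so the sidecar is an exact oracle for the recorded grouping. A
separate canned bundle reproduces a published field-blank worked example
(seven ammonia blanks below a 0.1 mg/l threshold; eleven TP blanks against
0.01 mg/l with a single at-threshold miss) as an exact target for the
acceptance arithmetic.

What passing these tests shows: the evaluators, tabulators, and screens
compute exactly what the formulas above say on data of this shape. What it
does not show: robustness to the messiness of real spreadsheets (mixed
encodings, free-text vocabularies, multi-year calendars, heteroscedastic or
heavy-tailed values), which the strict validator intentionally pushes back
onto the data-entry loop rather than repairing silently.

## Numerical and degenerate-input choices

* Quantiles: NumPy default (linear interpolation), identical in
  implementation and oracle.
* A group of identical values has IQR 0: bounds collapse onto the value and
  nothing flags.
* `percent_acceptance` uses `floor(x + 0.5)` because Python's `round` is
  banker's rounding.
* Empty accuracy criteria produce empty report sections, not errors;
  requesting a check type absent from the data yields an empty table.
* Report bodies contain no timestamps; identical bundles render
  byte-identical Markdown/HTML, and identical bundles produce identical
  workbook sheet contents.
* Report formats are Markdown and HTML; failing frequency/completeness rows
  are marked with a textual `MISS` plus a color-blind-friendly highlight in
  HTML so the flag survives uncolored formats.

## Limitations

Single reporting unit per parameter (no unit conversion, by design);
discrete samples only (no continuous sensor streams); no trend tests or
models behind the summary views; no upload or server-side validation against
WQX domain lists; thresholds shipped as editable examples, not as regulatory
facts for any particular jurisdiction.
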