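"""Evaluation of QC samples against data-quality objectives.

Five QC check types are recognized, matching the five-column summary layout
used in QC reports (calibration checks fold into the spike column):

* **Field/Lab Blanks** — an empty sample must read below a threshold; a
  censored (``BDL``) result is a hit, and for a strict ``<`` criterion a
  value *equal* to the threshold is a miss.
* **Field/Lab Duplicates** — a pair of measurements must agree.  The
  precision statistic for a percent criterion is the relative percent
  difference, ``RPD = 100 * |v - r| / mean(v, r)``; absolute criteria compare
  ``|v - r|`` directly.  Field-duplicate pairs live in the same results row,
  with the second member in the "QC Reference Value" column.
* **Lab Spikes / Instrument Checks** — a measurement of a known quantity
  (the QC reference value) must be close to it: percent criteria compare
  ``100 * |v - r| / r``, i.e. the percent deviation from full recovery.

Every QC record yields exactly one hit/miss verdict or one logged exclusion
notice; nothing is silently dropped.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Sequence

import pandas as pd

from .config import CHECK_TYPES, CHECK_TYPE_TO_RULE
from .criteria import Criterion, is_censored
from .render import doc_to_html, doc_to_markdown
from .tabular_io import AccuracyRule, InputBundle, select_rule

logger = logging.getLogger(__name__)

__all__ = [
    "QcIndividualResult",
    "percent_acceptance",
    "eval_blank",
    "eval_duplicate",
    "eval_spike",
    "qc_individual",
    "tab_accuracy",
    "eval_frequency",
    "eval_completeness",
    "assemble_report",
]

NO_DATA = "-"


def percent_acceptance(n_checks: int, n_misses: int) -> int | str:
    """Percent of QC checks that passed, as the nearest integer.

    Returns the no-data marker ``"-"`` when there are no checks.  Rounding is
    half away from zero so displayed percents are stable (90.909 -> 91,
    85.714 -> 86, x.5 always rounds up for the non-negative inputs here).
    """
    if n_checks < 0 or n_misses < 0:
        raise ValueError("counts must be non-negative")
    if n_misses > n_checks:
        raise ValueError("misses cannot exceed checks")
    if n_checks == 0:
        return NO_DATA
    return int(math.floor(100.0 * (n_checks - n_misses) / n_checks + 0.5))


@dataclass
class QcIndividualResult:
    """One QC record's verdict against its criterion (detailed-table row)."""

    check_type: str
    parameter: str
    date: str
    site: str
    result_display: str
    threshold_display: str
    verdict: str  # "hit" | "miss"


def _fmt_value(value: str, unit: str) -> str:
    v = value.strip()
    return v if is_censored(v) else f"{v} {unit}".strip()


def _fmt_threshold(criterion: Criterion, unit: str) -> str:
    if criterion.kind == "censored":
        return criterion.token
    mag = f"{criterion.magnitude:g}"
    return f"{mag}%" if criterion.kind == "percent" else f"{mag} {unit}".strip()


def _numeric(token: str) -> float | None:
    try:
        return float(token)
    except ValueError:
        return None


def _substitute(token: str, rule: AccuracyRule) -> float | None:
    """Numeric stand-in for a censored value: BDL -> MDL/2, AQL -> UQL."""
    t = token.strip().upper()
    if t == "BDL":
        return None if rule.mdl is None else rule.mdl / 2.0
    if t == "AQL":
        return rule.uql
    return _numeric(token)


# ---------------------------------------------------------------------------
# Single-record evaluators


def eval_blank(
    value: str,
    rule: AccuracyRule,
    which: str,
    *,
    parameter: str = "",
    date: str = "",
    site: str = "",
    unit: str = "",
) -> QcIndividualResult | None:
    """Evaluate one blank sample; returns None (with a notice) if no criterion."""
    col = "Field Blank" if which == "field" else "Lab Blank"
    check_type = "Field Blanks" if which == "field" else "Lab Blanks"
    criterion = rule.criteria.get(col)
    if criterion is None:
        logger.info("no %s criterion for %s; blank record excluded", col, rule.parameter)
        return None
    if criterion.kind == "censored":
        verdict = "hit" if is_censored(value) else "miss"
    elif is_censored(value):
        verdict = "hit"  # censored blank cannot exceed a detection threshold
    else:
        v = _numeric(value)
        if v is None:
            logger.warning("non-numeric blank value %r excluded", value)
            return None
        verdict = "hit" if criterion.check(v) else "miss"
    return QcIndividualResult(
        check_type=check_type,
        parameter=parameter or rule.parameter,
        date=date,
        site=site,
        result_display=_fmt_value(value, unit),
        threshold_display=_fmt_threshold(criterion, unit),
        verdict=verdict,
    )


def eval_duplicate(
    value: str,
    reference: str,
    rule: AccuracyRule,
    which: str,
    *,
    parameter: str = "",
    date: str = "",
    site: str = "",
    unit: str = "",
) -> QcIndividualResult | None:
    """Evaluate one duplicate pair for precision.

    Both-censored pairs are hits (the members are indistinguishable).  A
    mixed censored/numeric pair substitutes MDL/2 or UQL for the censored
    member before comparison, logging the substitution.  A zero pair mean
    under a percent criterion falls back to requiring exact equality.
    """
    col = "Field Duplicate" if which == "field" else "Lab Duplicate"
    check_type = "Field Duplicates" if which == "field" else "Lab Duplicates"
    criterion = rule.criteria.get(col)
    if criterion is None:
        logger.info("no %s criterion for %s; duplicate excluded", col, rule.parameter)
        return None

    disp = f"{_fmt_value(value, unit)} / {_fmt_value(reference, unit)}"
    if is_censored(value) and is_censored(reference):
        verdict = "hit"
    else:
        pair = []
        for tok in (value, reference):
            if is_censored(tok):
                sub = _substitute(tok, rule)
                if sub is None:
                    logger.warning(
                        "censored duplicate member %r for %s lacks an MDL/UQL; excluded",
                        tok,
                        rule.parameter,
                    )
                    return None
                logger.info("substituted %s for censored %s (%s)", sub, tok, rule.parameter)
                pair.append(sub)
            else:
                v = _numeric(tok)
                if v is None:
                    logger.warning("non-numeric duplicate member %r excluded", tok)
                    return None
                pair.append(v)
        v, r = pair
        if criterion.kind == "censored":
            verdict = "hit" if is_censored(value) and is_censored(reference) else "miss"
        elif criterion.kind == "percent":
            mean = (v + r) / 2.0
            if mean == 0:
                verdict = "hit" if v == r else "miss"
            else:
                rpd = 100.0 * abs(v - r) / abs(mean)
                verdict = "hit" if criterion.check(rpd) else "miss"
        else:
            verdict = "hit" if criterion.check(abs(v - r)) else "miss"
    return QcIndividualResult(
        check_type=check_type,
        parameter=parameter or rule.parameter,
        date=date,
        site=site,
        result_display=disp,
        threshold_display=_fmt_threshold(criterion, unit),
        verdict=verdict,
    )


def eval_spike(
    value: str,
    reference: str,
    rule: AccuracyRule,
    *,
    parameter: str = "",
    date: str = "",
    site: str = "",
    unit: str = "",
) -> QcIndividualResult | None:
    """Evaluate one spike/instrument check against its known quantity."""
    criterion = rule.criteria.get("Spike/Check Accuracy")
    if criterion is None:
        logger.info("no spike criterion for %s; record excluded", rule.parameter)
        return None
    v, r = _numeric(value), _numeric(reference)
    if v is None or r is None:
        logger.warning(
            "spike check needs numeric value and known quantity; got %r / %r", value, reference
        )
        return None
    if criterion.kind == "percent":
        if r == 0:
            logger.warning("spike known quantity is zero for %s; excluded", rule.parameter)
            return None
        stat = 100.0 * abs(v - r) / abs(r)
    else:
        stat = abs(v - r)
    return QcIndividualResult(
        check_type="Lab Spikes / Instrument Checks",
        parameter=parameter or rule.parameter,
        date=date,
        site=site,
        result_display=f"{_fmt_value(value, unit)} / {_fmt_value(reference, unit)}",
        threshold_display=_fmt_threshold(criterion, unit),
        verdict="hit" if criterion.check(stat) else "miss",
    )


# ---------------------------------------------------------------------------
# Whole-table evaluation

_BLANK_ACTIVITY = {
    "Quality Control Sample-Field Blank": "field",
    "Quality Control Sample-Lab Blank": "lab",
}
_SPIKE_ACTIVITY = (
    "Quality Control Sample-Lab Spike",
    "Quality Control-Calibration Check",
)
_LAB_DUP_ACTIVITY = "Quality Control Sample-Lab Duplicate"


def _rule_for(
    rules: dict[str, list[AccuracyRule]], parameter: str, value: str
) -> AccuracyRule | None:
    plist = rules.get(parameter)
    if not plist:
        return None
    v = _numeric(value) if not is_censored(value) else None
    return select_rule(plist, v)


def qc_individual(
    bundle: InputBundle, accchk: Sequence[str] | None = None
) -> list[QcIndividualResult]:
    """Evaluate every QC record in the bundle's results table.

    Returns one verdict per QC record, ordered by check type, parameter
    (accuracy-file order), then date.  Records without an applicable
    criterion are excluded with a logged notice.
    """
    res = bundle.results
    rules = bundle.rules
    regular = set(bundle.config["regular_activity_types"])
    wanted = set(accchk) if accchk else set(CHECK_TYPES)
    out: list[QcIndividualResult] = []

    for _, row in res.iterrows():
        at = row["Activity Type"]
        p = row["Characteristic Name"]
        value = row["Result Value"]
        ref = row["QC Reference Value"].strip()
        unit = row["Result Unit"]
        date = row["Activity Start Date"]
        site = row["Monitoring Location ID"]
        rule = _rule_for(rules, p, value)
        if at in _BLANK_ACTIVITY:
            which = _BLANK_ACTIVITY[at]
            ct = "Field Blanks" if which == "field" else "Lab Blanks"
            if ct not in wanted:
                continue
            if rule is None:
                logger.info("no accuracy rule for %s; blank excluded", p)
                continue
            r = eval_blank(value, rule, which, parameter=p, date=date, site=site, unit=unit)
            if r:
                out.append(r)
        elif at == _LAB_DUP_ACTIVITY:
            if "Lab Duplicates" not in wanted:
                continue
            if rule is None:
                logger.info("no accuracy rule for %s; lab duplicate excluded", p)
                continue
            if not ref:
                logger.warning("lab duplicate without QC Reference Value excluded (%s)", p)
                continue
            r = eval_duplicate(value, ref, rule, "lab", parameter=p, date=date, site=site, unit=unit)
            if r:
                out.append(r)
        elif at in _SPIKE_ACTIVITY:
            if "Lab Spikes / Instrument Checks" not in wanted:
                continue
            if rule is None:
                logger.info("no accuracy rule for %s; spike excluded", p)
                continue
            if not ref:
                logger.warning("spike check without QC Reference Value excluded (%s)", p)
                continue
            r = eval_spike(value, ref, rule, parameter=p, date=date, site=site, unit=unit)
            if r:
                out.append(r)
        elif at in regular and ref:
            # field duplicate entered as a qualified sample in the same row
            if "Field Duplicates" not in wanted:
                continue
            if rule is None:
                logger.info("no accuracy rule for %s; field duplicate excluded", p)
                continue
            r = eval_duplicate(value, ref, rule, "field", parameter=p, date=date, site=site, unit=unit)
            if r:
                out.append(r)

    param_order = {p: i for i, p in enumerate(dict.fromkeys(bundle.accuracy["Parameter"]))}
    type_order = {t: i for i, t in enumerate(CHECK_TYPES)}
    out.sort(key=lambda r: (type_order[r.check_type], param_order.get(r.parameter, 99), r.date))
    return out


def _summary_counts(
    individual: Sequence[QcIndividualResult],
) -> pd.DataFrame:
    rows = []
    seen: dict[tuple[str, str], list[int]] = {}
    for r in individual:
        key = (r.check_type, r.parameter)
        if key not in seen:
            seen[key] = [0, 0]
        seen[key][0] += 1
        seen[key][1] += r.verdict == "miss"
    for (ct, p), (n, m) in seen.items():
        pct = percent_acceptance(n, m)
        rows.append(
            {
                "Type": ct,
                "Parameter": p,
                "Number of QC Checks": n,
                "Number of Misses": m,
                "% Acceptance": f"{pct}%" if pct != NO_DATA else NO_DATA,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["Type", "Parameter", "Number of QC Checks", "Number of Misses", "% Acceptance"],
    )


def tab_accuracy(
    bundle: InputBundle,
    type: str = "summary",
    accchk: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Accuracy QC tables: ``individual``, ``summary``, or ``percent`` views.

    * ``individual`` — one row per QC record with its verdict (detailed view).
    * ``summary`` — checks/misses/percent acceptance per check type and
      parameter, in the five-check-type report order.
    * ``percent`` — parameter x check-type matrix of acceptance percents with
      ``"-"`` where no QC records exist.
    """
    bundle.require("qc_reporting" if type == "percent" else "analysis")
    individual = qc_individual(bundle, accchk)
    if type == "individual":
        return pd.DataFrame(
            [
                {
                    "Check": r.check_type,
                    "Parameter": r.parameter,
                    "Date": r.date,
                    "Site": r.site,
                    "Result": r.result_display,
                    "Threshold": r.threshold_display,
                    "Hit/Miss": "MISS" if r.verdict == "miss" else "",
                }
                for r in individual
            ],
            columns=["Check", "Parameter", "Date", "Site", "Result", "Threshold", "Hit/Miss"],
        )
    summary = _summary_counts(individual)
    if type == "summary":
        return summary
    if type != "percent":
        raise ValueError(f"unknown table type {type!r}")
    params = list(dict.fromkeys(bundle.accuracy["Parameter"]))
    matrix = pd.DataFrame(NO_DATA, index=params, columns=list(CHECK_TYPES))
    for _, row in summary.iterrows():
        matrix.loc[row["Parameter"], row["Type"]] = row["% Acceptance"]
    matrix.index.name = "Parameter"
    return matrix.reset_index()


# ---------------------------------------------------------------------------
# Frequency & completeness


def _qualified_mask(res: pd.DataFrame, config: dict[str, Any]) -> pd.Series:
    regular = set(config["regular_activity_types"])
    mask = res["Activity Type"].isin(regular) & (
        res["QC Reference Value"].str.strip() != ""
    )
    qcol = config.get("qualifier_column")
    if qcol and qcol in res.columns:
        mask |= res[qcol].str.strip() != ""
    return mask


def eval_frequency(bundle: InputBundle) -> pd.DataFrame:
    """Observed vs required QC frequency per parameter and check type.

    The denominator is the count of that parameter's regular (non-QC,
    non-qualified) records; the numerator counts QC checks of the given type,
    with same-row duplicate pairs counted as one check.  Check types without
    a required percent in the frequency DQOs are omitted.
    """
    bundle.require("qc_reporting")
    res = bundle.results
    cfg = bundle.config
    regular = set(cfg["regular_activity_types"])
    qualified = _qualified_mask(res, cfg)
    is_regular = res["Activity Type"].isin(regular) & ~qualified

    frecom = bundle.frecom.set_index("Parameter")
    rows = []
    for p in frecom.index:
        sub = res[res["Characteristic Name"] == p]
        sub_qual = qualified[sub.index]
        n_regular = int((sub["Activity Type"].isin(regular) & ~sub_qual).sum())
        counts = {
            "Field Duplicates": int(sub_qual.sum()),
            "Lab Duplicates": int((sub["Activity Type"] == _LAB_DUP_ACTIVITY).sum()),
            "Field Blanks": int(
                (sub["Activity Type"] == "Quality Control Sample-Field Blank").sum()
            ),
            "Lab Blanks": int(
                (sub["Activity Type"] == "Quality Control Sample-Lab Blank").sum()
            ),
            "Lab Spikes / Instrument Checks": int(
                sub["Activity Type"].isin(_SPIKE_ACTIVITY).sum()
            ),
        }
        for ct in CHECK_TYPES:
            req_cell = str(frecom.loc[p, CHECK_TYPE_TO_RULE[ct]]).strip()
            if req_cell in ("", "nan", NO_DATA):
                continue
            required = float(req_cell)
            n_qc = counts[ct]
            if n_regular == 0:
                observed, met = None, None
            else:
                observed = 100.0 * n_qc / n_regular
                met = observed >= required
            rows.append(
                {
                    "Parameter": p,
                    "Check": ct,
                    "Number of Regular Samples": n_regular,
                    "Number of QC Checks": n_qc,
                    "Frequency %": round(observed, 1) if observed is not None else NO_DATA,
                    "Required %": required,
                    "Met": met,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "Parameter",
            "Check",
            "Number of Regular Samples",
            "Number of QC Checks",
            "Frequency %",
            "Required %",
            "Met",
        ],
    )


def eval_completeness(bundle: InputBundle) -> pd.DataFrame:
    """Proportion of each parameter's records usable as regular data.

    ``% Completeness = 100 * (n_records - n_qualified) / n_records`` where
    qualified records are those carrying a paired QC value (or flagged by the
    configured qualifier column) among the regular rows.
    """
    bundle.require("qc_reporting")
    res = bundle.results
    cfg = bundle.config
    regular = set(cfg["regular_activity_types"])
    qualified = _qualified_mask(res, cfg)

    frecom = bundle.frecom.set_index("Parameter")
    rows = []
    for p in frecom.index:
        req_cell = str(frecom.loc[p, "% Completeness"]).strip()
        if req_cell in ("", "nan", NO_DATA):
            continue
        required = float(req_cell)
        sub = res[res["Characteristic Name"] == p]
        n_records = int(sub["Activity Type"].isin(regular).sum())
        n_qualified = int(qualified[sub.index].sum())
        if n_records == 0:
            pct, met = NO_DATA, None
        else:
            pct = round(100.0 * (n_records - n_qualified) / n_records, 1)
            met = pct >= required
        rows.append(
            {
                "Parameter": p,
                "Number of Records": n_records,
                "Number of Qualified": n_qualified,
                "% Completeness": pct,
                "Required %": required,
                "Met": met,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "Parameter",
            "Number of Records",
            "Number of Qualified",
            "% Completeness",
            "Required %",
            "Met",
        ],
    )


# ---------------------------------------------------------------------------
# QC report assembly


def _miss_mark(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    if "Met" in out.columns:
        out["Met"] = out["Met"].map(lambda m: "MISS" if m is False else ("" if m is None else "OK"))
    return out


def assemble_report(
    bundle: InputBundle,
    output_dir: str | Path,
    format: str = "md",
    organization: str = "",
    notes: str = "",
) -> Path:
    """Assemble the full QC report and write it to *output_dir*.

    Section order: data-quality objectives (accuracy; frequency &
    completeness), frequency results, completeness results, accuracy summary,
    accuracy percent matrix, then one detailed table per check type.
    Parameters failing a frequency or completeness objective are marked
    ``MISS`` so the flag survives uncolored formats.  Formats: ``md`` and
    ``html`` (``md`` also writes the HTML rendering's source).
    """
    bundle.require("qc_reporting")
    if format not in ("md", "html"):
        raise ValueError(
            f"unsupported report format {format!r}: available formats are 'md' and 'html'"
        )
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)

    doc: list[tuple[str, Any]] = [("title", "Quality Control Report")]
    if organization:
        doc.append(("para", f"Organization: {organization}"))
    if notes:
        doc.append(("para", f"Notes: {notes}"))

    doc.append(("heading", "Data Quality Objectives: Accuracy"))
    doc.append(("table", bundle.accuracy))
    doc.append(("heading", "Data Quality Objectives: Frequency and Completeness"))
    doc.append(("table", bundle.frecom))

    doc.append(("heading", "QC Frequency Results"))
    doc.append(("table", _miss_mark(eval_frequency(bundle))))
    doc.append(("heading", "QC Completeness Results"))
    doc.append(("table", _miss_mark(eval_completeness(bundle))))

    doc.append(("heading", "Accuracy Summary"))
    doc.append(("table", tab_accuracy(bundle, "summary")))
    doc.append(("heading", "Accuracy Percent Acceptance"))
    doc.append(("table", tab_accuracy(bundle, "percent")))

    individual = tab_accuracy(bundle, "individual")
    for ct in CHECK_TYPES:
        sub = individual[individual["Check"] == ct].drop(columns=["Check"])
        doc.append(("heading", f"Individual Results: {ct}"))
        if sub.empty:
            doc.append(("para", "No QC records of this type in the results file."))
        else:
            doc.append(("table", sub))

    if format == "html":
        path = output_dir / "qc_report.html"
        path.write_text(doc_to_html(doc))
    else:
        path = output_dir / "qc_report.md"
        path.write_text(doc_to_markdown(doc))
    print(f"Report created successfully! File located at {path}")
    return path
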