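"""Reading, checking, and bundling the five monitoring input tables.

The workflow is deliberately strict: every input file must match its template
exactly, and the read functions run a named check suite over the raw cells
before anything downstream sees the data.  Checks are reported in a fixed
order; the first failure aborts the read with a row-addressed message so the
user can fix the spreadsheet and re-import (an iterative loop).  Row indices
in messages are 1-based over data rows, i.e. the header row is excluded; set
``row_index_offset: 1`` in the config for spreadsheet-style addressing.

All tables are held as string-valued :class:`pandas.DataFrame` objects with
``""`` for missing cells, so writing and re-reading a table round-trips every
cell (including the ``BDL``/``AQL`` censoring tokens) bit-exact.
"""

from __future__ import annotations

import datetime as _dt
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Sequence

import numpy as np
import pandas as pd

from .config import (
    ACCURACY_COLUMNS,
    FRECOM_COLUMNS,
    RESULTS_COLUMNS,
    SITES_COLUMNS,
    default_config,
)
from .criteria import (
    Criterion,
    CriterionError,
    is_censored,
    parse_criterion,
    parse_value_range,
)

__all__ = [
    "CheckOutcome",
    "ChecksFailedError",
    "BundleError",
    "AccuracyRule",
    "InputBundle",
    "read_results",
    "read_accuracy",
    "read_frecom",
    "read_sites",
    "read_wqx",
    "results_view",
    "bundle",
    "load_table",
    "write_table",
    "parse_accuracy_rules",
    "normalize_date",
]


# ---------------------------------------------------------------------------
# Table loading / writing


def load_table(path_or_table: str | Path | pd.DataFrame) -> pd.DataFrame:
    """Load a CSV or XLSX table (or pass through a DataFrame) as strings.

    Every cell becomes a Python ``str``; missing cells become ``""``.  Excel
    date/number cells are stringified with their natural representation and
    later normalized by the check/format pipeline.
    """
    if isinstance(path_or_table, pd.DataFrame):
        df = path_or_table.copy()
    else:
        path = Path(path_or_table)
        if not path.exists():
            raise FileNotFoundError(f"input file not found: {path}")
        if path.suffix.lower() in (".xlsx", ".xlsm"):
            df = pd.read_excel(path, dtype=object)
        else:
            df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return _stringify(df)


def _stringify(df: pd.DataFrame) -> pd.DataFrame:
    def conv(v: Any) -> str:
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return ""
        if isinstance(v, pd.Timestamp) or isinstance(v, _dt.datetime):
            if v.hour == v.minute == v.second == 0:
                return v.strftime("%Y-%m-%d")
            return v.strftime("%Y-%m-%d %H:%M:%S")
        if isinstance(v, _dt.time):
            return v.strftime("%H:%M")
        if isinstance(v, float) and v == int(v) and abs(v) < 1e15:
            return str(int(v))
        s = str(v)
        return "" if s.lower() == "nan" else s

    out = df.map(conv)
    out.columns = [str(c) for c in df.columns]
    return out.reset_index(drop=True)


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a string table to CSV or XLSX; XLSX cells are written as text."""
    path = Path(path)
    if path.suffix.lower() == ".xlsx":
        from openpyxl import Workbook

        wb = Workbook()
        ws = wb.active
        ws.append(list(df.columns))
        for row in df.itertuples(index=False):
            cells = []
            for v in row:
                v = "" if v is None else str(v)
                cells.append(v if v != "" else None)
            ws.append(cells)
        for col in ws.iter_cols():
            for cell in col:
                cell.number_format = "@"
        wb.save(path)
    else:
        df.to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# Check outcomes


@dataclass
class CheckOutcome:
    """One named validation check with status and row-addressed detail."""

    check_name: str
    status: str  # "ok" | "warn" | "fail"
    message: str = ""
    offending_values: list[str] = field(default_factory=list)
    offending_rows: list[int] = field(default_factory=list)

    def __str__(self) -> str:
        line = f"{self.check_name}... {self.status.upper() if self.status != 'ok' else 'OK'}"
        if self.message:
            line += f"\n{self.message}"
        return line


class ChecksFailedError(ValueError):
    """Raised when a check suite aborts; carries the outcomes produced so far."""

    def __init__(self, outcomes: list[CheckOutcome]):
        self.outcomes = outcomes
        failed = outcomes[-1]
        super().__init__(f"{failed.check_name}...\n{failed.message}")


class BundleError(ValueError):
    """A bundle is missing a component required by the requested workflow step."""


def _rows_str(rows: Sequence[int]) -> str:
    return ", ".join(str(r) for r in rows)


# ---------------------------------------------------------------------------
# Date / time normalization

_ISO_RE = re.compile(r"^\d{4}-\d{2}-\d{2}$")
_US_RE = re.compile(r"^(\d{1,2})/(\d{1,2})/(\d{4})$")
_ISO_TS_RE = re.compile(r"^(\d{4}-\d{2}-\d{2})[ T]\d{2}:\d{2}(:\d{2})?$")
_SERIAL_RE = re.compile(r"^\d{4,6}$")
_EXCEL_EPOCH = _dt.date(1899, 12, 30)


def normalize_date(cell: str) -> str | None:
    """Normalize a date cell to ``YYYY-MM-DD``; return None if unparseable.

    Accepts ISO dates, ISO timestamps, ``M/D/YYYY``, and spreadsheet serial
    day numbers.  Idempotent on already-normalized values.
    """
    text = cell.strip()
    if not text:
        return None
    if _ISO_RE.match(text):
        try:
            _dt.date.fromisoformat(text)
            return text
        except ValueError:
            return None
    m = _ISO_TS_RE.match(text)
    if m:
        return normalize_date(m.group(1))
    m = _US_RE.match(text)
    if m:
        mo, da, yr = (int(g) for g in m.groups())
        try:
            return _dt.date(yr, mo, da).isoformat()
        except ValueError:
            return None
    if _SERIAL_RE.match(text):
        serial = int(text)
        if 365 < serial < 200000:
            return (_EXCEL_EPOCH + _dt.timedelta(days=serial)).isoformat()
    return None


def _is_number(text: str) -> bool:
    try:
        float(text)
        return True
    except ValueError:
        return False


# ---------------------------------------------------------------------------
# Results file: the fifteen-check suite

_C = "Characteristic Name"
_RV = "Result Value"
_QC = "QC Reference Value"
_RU = "Result Unit"
_AT = "Activity Type"
_AD = "Activity Start Date"
_ATM = "Activity Start Time"
_DM = "Activity Depth/Height Measure"
_DU = "Activity Depth/Height Unit"
_RD = "Activity Relative Depth Name"


def read_results(
    path_or_table: str | Path | pd.DataFrame,
    config: dict[str, Any] | None = None,
    strict: bool = False,
    verbose: bool = False,
) -> tuple[pd.DataFrame, list[CheckOutcome]]:
    """Read and validate a results table; return (normalized table, outcomes).

    Runs the fifteen named checks in fixed order, aborting on the first
    failure with :class:`ChecksFailedError`.  The deep-sample depth check and
    missing sample times produce warnings unless ``strict`` promotes them to
    failures.  On success, dates are normalized to ``YYYY-MM-DD``.
    """
    cfg = config or default_config()
    df = load_table(path_or_table)
    offset = int(cfg.get("row_index_offset", 0))
    outcomes: list[CheckOutcome] = []

    def rows_of(mask: Iterable[bool]) -> list[int]:
        return [i + 1 + offset for i, bad in enumerate(mask) if bad]

    def ok(name: str) -> None:
        outcomes.append(CheckOutcome(name, "ok"))
        if verbose:
            print(f"{name}... OK")

    def warn(name: str, message: str, values: list[str], rows: list[int]) -> None:
        status = "fail" if strict else "warn"
        outcomes.append(CheckOutcome(name, status, message, values, rows))
        if verbose:
            print(f"{name}... {'Error' if strict else 'Warning'}: {message}")
        if strict:
            raise ChecksFailedError(outcomes)

    def fail(name: str, message: str, values: list[str], rows: list[int]) -> None:
        outcomes.append(CheckOutcome(name, "fail", message, values, rows))
        raise ChecksFailedError(outcomes)

    if verbose:
        print("Running checks on results data...")

    # 1. column names are recognized
    name = "Checking column names"
    unknown = [c for c in df.columns if c not in RESULTS_COLUMNS]
    if unknown:
        fail(name, f"Unrecognized column name(s): {', '.join(unknown)}", unknown, [])
    ok(name)

    # 2. all required columns present
    name = "Checking all required columns are present"
    missing = [c for c in RESULTS_COLUMNS if c not in df.columns]
    if missing:
        fail(name, f"Missing column(s): {', '.join(missing)}", missing, [])
    df = df[list(RESULTS_COLUMNS)]
    ok(name)

    # 3. valid activity types
    name = "Checking valid Activity Types"
    valid_at = set(cfg["activity_types"])
    bad_mask = [v not in valid_at for v in df[_AT]]
    if any(bad_mask):
        rows = rows_of(bad_mask)
        vals = list(dict.fromkeys(df[_AT][bad_mask]))
        fail(
            name,
            f"Incorrect Activity Type found: {', '.join(vals)} in row(s) {_rows_str(rows)}",
            vals,
            rows,
        )
    ok(name)

    # 4. date formats (missing times warn, after dates pass)
    name = "Checking Activity Start Date formats"
    norm = [normalize_date(v) for v in df[_AD]]
    bad_mask = [n is None for n in norm]
    if any(bad_mask):
        rows = rows_of(bad_mask)
        vals = list(dict.fromkeys(df[_AD][bad_mask]))
        fail(
            name,
            f"Unrecognized date format: {', '.join(vals)} in row(s) {_rows_str(rows)}",
            vals,
            rows,
        )
    missing_time = [t.strip() == "" for t in df[_ATM]]
    if any(missing_time):
        rows = rows_of(missing_time)
        warn(
            name,
            f"Missing Activity Start Time in row(s) {_rows_str(rows)}",
            [],
            rows,
        )
    else:
        ok(name)

    # 5. depth data present on field rows
    name = "Checking depth data present"
    regular = set(cfg["regular_activity_types"])
    bad_mask = [
        at in regular and dm.strip() == "" and rd.strip() == ""
        for at, dm, rd in zip(df[_AT], df[_DM], df[_RD])
    ]
    if any(bad_mask):
        rows = rows_of(bad_mask)
        fail(
            name,
            f"Activity Depth/Height Measure or Activity Relative Depth Name "
            f"required in row(s) {_rows_str(rows)}",
            [],
            rows,
        )
    ok(name)

    # 6. depth measures numeric
    name = "Checking for non-numeric values in Activity Depth/Height Measure"
    bad_mask = [v.strip() != "" and not _is_number(v) for v in df[_DM]]
    if any(bad_mask):
        rows = rows_of(bad_mask)
        vals = list(dict.fromkeys(df[_DM][bad_mask]))
        fail(
            name,
            f"Non-numeric Activity Depth/Height Measure: {', '.join(vals)} "
            f"in row(s) {_rows_str(rows)}",
            vals,
            rows,
        )
    ok(name)

    # 7. depth units valid and present whenever a measure is present
    name = "Checking Activity Depth/Height Unit"
    valid_du = set(cfg["depth_units"])
    bad_mask = [
        (dm.strip() != "" and du.strip() == "")
        or (du.strip() != "" and du.strip() not in valid_du)
        for dm, du in zip(df[_DM], df[_DU])
    ]
    if any(bad_mask):
        rows = rows_of(bad_mask)
        vals = list(dict.fromkeys(v for v in df[_DU][bad_mask]))
        fail(
            name,
            f"Incorrect Activity Depth/Height Unit: {', '.join(v or '<blank>' for v in vals)} "
            f"in row(s) {_rows_str(rows)}",
            vals,
            rows,
        )
    ok(name)

    # 8. relative depth names from the controlled vocabulary
    name = "Checking Activity Relative Depth Name formats"
    valid_rd = set(cfg["relative_depth_names"])
    bad_mask = [v.strip() != "" and v.strip() not in valid_rd for v in df[_RD]]
    if any(bad_mask):
        rows = rows_of(bad_mask)
        vals = list(dict.fromkeys(df[_RD][bad_mask]))
        fail(
            name,
            f"Incorrect Activity Relative Depth Name: {', '.join(vals)} "
            f"in row(s) {_rows_str(rows)}",
            vals,
            rows,
        )
    ok(name)

    # 9. unusually deep samples (warning: deep samples can be legitimate)
    name = "Checking values in Activity Depth/Height Measure > 1 m / 3.3 ft"
    deep_mask = []
    for dm, du in zip(df[_DM], df[_DU]):
        if dm.strip() == "" or not _is_number(dm):
            deep_mask.append(False)
            continue
        v = float(dm)
        limit = 3.3 if du.strip() == "ft" else 1.0
        deep_mask.append(v > limit)
    if any(deep_mask):
        rows = rows_of(deep_mask)
        warn(name, f"Depth value > 1 m / 3.3 ft in row(s) {_rows_str(rows)}", [], rows)
    else:
        ok(name)

    # 10. characteristic names in the parameter dictionary
    name = "Checking Characteristic Name formats"
    params = set(cfg["parameters"])
    bad_mask = [v not in params for v in df[_C]]
    if any(bad_mask):
        rows = rows_of(bad_mask)
        vals = list(dict.fromkeys(df[_C][bad_mask]))
        fail(
            name,
            f"Incorrect Characteristic Name found: {', '.join(vals)} "
            f"in row(s) {_rows_str(rows)}",
            vals,
            rows,
        )
    ok(name)

    # 11. result values numeric or censored; negatives only where meaningful
    name = "Checking Result Values"
    neg_ok = set(cfg["negative_ok_parameters"])
    bad_mask = []
    for v, p in zip(df[_RV], df[_C]):
        t = v.strip()
        if t == "":
            bad_mask.append(True)
        elif is_censored(t):
            bad_mask.append(False)
        elif not _is_number(t):
            bad_mask.append(True)
        else:
            bad_mask.append(float(t) < 0 and p not in neg_ok)
    if any(bad_mask):
        rows = rows_of(bad_mask)
        vals = list(dict.fromkeys(v or "<blank>" for v in df[_RV][bad_mask]))
        fail(
            name,
            f"Incorrect Result Value found: {', '.join(vals)} in row(s) {_rows_str(rows)}",
            vals,
            rows,
        )
    ok(name)

    # 12. QC reference values numeric or censored when present
    name = "Checking QC Reference Values"
    bad_mask = [
        v.strip() != "" and not is_censored(v) and not _is_number(v) for v in df[_QC]
    ]
    if any(bad_mask):
        rows = rows_of(bad_mask)
        vals = list(dict.fromkeys(df[_QC][bad_mask]))
        fail(
            name,
            f"Incorrect QC Reference Value found: {', '.join(vals)} "
            f"in row(s) {_rows_str(rows)}",
            vals,
            rows,
        )
    ok(name)

    # 13. result units present
    name = "Checking for missing entries for Result Unit"
    bad_mask = [v.strip() == "" for v in df[_RU]]
    if any(bad_mask):
        rows = rows_of(bad_mask)
        fail(name, f"Missing Result Unit in row(s) {_rows_str(rows)}", [], rows)
    ok(name)

    # 14. one unit of measurement per parameter
    name = "Checking if more than one unit per Characteristic Name"
    multi = (
        df.groupby(_C)[_RU].agg(lambda s: len(set(s))).loc[lambda s: s > 1].index.tolist()
    )
    if multi:
        fail(
            name,
            f"More than one unit found for Characteristic Name: {', '.join(multi)}",
            multi,
            [],
        )
    ok(name)

    # 15. units acceptable for each parameter
    name = "Checking acceptable units for each entry in Characteristic Name"
    bad_mask = [
        u.strip() not in cfg["parameters"][p]["units"] for u, p in zip(df[_RU], df[_C])
    ]
    if any(bad_mask):
        rows = rows_of(bad_mask)
        vals = list(
            dict.fromkeys(f"{u} ({p})" for u, p in zip(df[_RU][bad_mask], df[_C][bad_mask]))
        )
        fail(
            name,
            f"Unacceptable Result Unit found: {', '.join(vals)} "
            f"in row(s) {_rows_str(rows)}",
            vals,
            rows,
        )
    ok(name)

    if verbose:
        print("All checks passed!")

    out = df.copy()
    out[_AD] = [normalize_date(v) for v in out[_AD]]
    return out, outcomes


# ---------------------------------------------------------------------------
# DQO accuracy


@dataclass(frozen=True)
class AccuracyRule:
    """Per-parameter accuracy data-quality objectives over one value range."""

    parameter: str
    mdl: float | None
    uql: float | None
    value_range: tuple[float, float] | None
    criteria: dict[str, Criterion | None]  # keyed by accuracy column name
    scale_hint: str  # "log" | "linear"
    order: int  # file order, breaks ties between overlapping ranges

    def applies_to(self, value: float) -> bool:
        if self.value_range is None:
            return True
        lo, hi = self.value_range
        return lo <= value <= hi

    def range_width(self) -> float:
        if self.value_range is None:
            return float("inf")
        lo, hi = self.value_range
        return hi - lo


def read_accuracy(
    path_or_table: str | Path | pd.DataFrame,
    config: dict[str, Any] | None = None,
) -> pd.DataFrame:
    """Read and validate the DQO accuracy table (raw strings preserved)."""
    cfg = config or default_config()
    df = load_table(path_or_table)
    missing = [c for c in ACCURACY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"accuracy file missing column(s): {', '.join(missing)}")
    params = set(cfg["parameters"])
    crit_cols = [
        "Field Duplicate",
        "Lab Duplicate",
        "Field Blank",
        "Lab Blank",
        "Spike/Check Accuracy",
    ]
    for i, row in df.iterrows():
        p = row["Parameter"]
        if p not in params:
            raise ValueError(
                f"accuracy file: unknown parameter {p!r} in row {i + 1}"
            )
        for col in ("MDL", "UQL"):
            v = row[col].strip()
            if v and not _is_number(v):
                raise ValueError(
                    f"accuracy file: non-numeric {col} {v!r} in row {i + 1}"
                )
        try:
            parse_value_range(row["Value Range"])
        except CriterionError as exc:
            raise ValueError(
                f"accuracy file: row {i + 1}, column 'Value Range': {exc}"
            ) from exc
        for col in crit_cols:
            cell = row[col]
            # strip a log token before parsing; "log" alone is a scale hint
            text = re.sub(r"\blog\b", "", cell, flags=re.I).strip()
            try:
                parse_criterion(text)
            except CriterionError as exc:
                raise ValueError(
                    f"accuracy file: row {i + 1}, column {col!r}: {exc}"
                ) from exc
    return df


def parse_accuracy_rules(
    accdf: pd.DataFrame, config: dict[str, Any] | None = None
) -> dict[str, list[AccuracyRule]]:
    """Parse a validated accuracy table into rules grouped by parameter."""
    rules: dict[str, list[AccuracyRule]] = {}
    crit_cols = [
        "Field Duplicate",
        "Lab Duplicate",
        "Field Blank",
        "Lab Blank",
        "Spike/Check Accuracy",
    ]
    for order, (_, row) in enumerate(accdf.iterrows()):
        has_log = any(
            re.search(r"\blog\b", row[c], flags=re.I) for c in crit_cols
        )
        criteria = {}
        for col in crit_cols:
            text = re.sub(r"\blog\b", "", row[col], flags=re.I).strip()
            criteria[col] = parse_criterion(text)
        rule = AccuracyRule(
            parameter=row["Parameter"],
            mdl=float(row["MDL"]) if row["MDL"].strip() else None,
            uql=float(row["UQL"]) if row["UQL"].strip() else None,
            value_range=parse_value_range(row["Value Range"]),
            criteria=criteria,
            scale_hint="log" if has_log else "linear",
            order=order,
        )
        rules.setdefault(rule.parameter, []).append(rule)
    return rules


def select_rule(
    rules: Sequence[AccuracyRule], value: float | None
) -> AccuracyRule | None:
    """Pick the rule whose value range covers *value*.

    The narrowest applicable range wins; ties break by file order.  With no
    value (censored result), the widest range (usually 'all') is used.
    """
    if not rules:
        return None
    if value is None:
        return min(rules, key=lambda r: (-r.range_width(), r.order))
    applicable = [r for r in rules if r.applies_to(value)]
    if not applicable:
        return None
    return min(applicable, key=lambda r: (r.range_width(), r.order))


# ---------------------------------------------------------------------------
# DQO frequency & completeness


def read_frecom(
    path_or_table: str | Path | pd.DataFrame,
    config: dict[str, Any] | None = None,
) -> pd.DataFrame:
    """Read and validate the frequency & completeness DQO table."""
    cfg = config or default_config()
    df = load_table(path_or_table)
    missing = [c for c in FRECOM_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"frequency/completeness file missing column(s): {', '.join(missing)}")
    params = set(cfg["parameters"])
    pct_cols = [c for c in FRECOM_COLUMNS if c != "Parameter"]
    for i, row in df.iterrows():
        if row["Parameter"] not in params:
            raise ValueError(
                f"frequency/completeness file: unknown parameter "
                f"{row['Parameter']!r} in row {i + 1}"
            )
        for col in pct_cols:
            v = row[col].strip()
            if v == "":
                continue
            if not _is_number(v) or not (0 <= float(v) <= 100):
                raise ValueError(
                    f"frequency/completeness file: row {i + 1}, column {col!r}: "
                    f"percent {v!r} outside [0, 100]"
                )
    return df


# ---------------------------------------------------------------------------
# Sites & WQX metadata


def read_sites(
    path_or_table: str | Path | pd.DataFrame,
    config: dict[str, Any] | None = None,
) -> pd.DataFrame:
    """Read and validate the site metadata table."""
    df = load_table(path_or_table)
    missing = [c for c in SITES_COLUMNS[:3] if c not in df.columns]
    if missing:
        raise ValueError(f"sites file missing column(s): {', '.join(missing)}")
    if "Location Group" not in df.columns:
        df["Location Group"] = ""
    ids = df["Monitoring Location ID"]
    dup = ids[ids.duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"sites file: duplicate Monitoring Location ID: {', '.join(dup)}")
    for i, row in df.iterrows():
        for col, lo, hi in (
            ("Monitoring Location Latitude", -90.0, 90.0),
            ("Monitoring Location Longitude", -180.0, 180.0),
        ):
            v = row[col].strip()
            if not _is_number(v) or not (lo <= float(v) <= hi):
                raise ValueError(
                    f"sites file: row {i + 1}, column {col!r}: "
                    f"value {v!r} outside [{lo}, {hi}]"
                )
    return df


def read_wqx(
    path_or_table: str | Path | pd.DataFrame,
    config: dict[str, Any] | None = None,
) -> pd.DataFrame:
    """Read per-parameter WQX submission metadata (open column set)."""
    cfg = config or default_config()
    df = load_table(path_or_table)
    if "Parameter" not in df.columns:
        raise ValueError("WQX metadata file missing 'Parameter' column")
    params = set(cfg["parameters"])
    unknown = [p for p in df["Parameter"] if p not in params]
    if unknown:
        raise ValueError(
            f"WQX metadata file: unknown parameter(s): {', '.join(sorted(set(unknown)))}"
        )
    dup = df["Parameter"][df["Parameter"].duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"WQX metadata file: duplicate parameter(s): {', '.join(dup)}")
    return df


# ---------------------------------------------------------------------------
# Troubleshooting view


def results_view(
    path_or_table: str | Path | pd.DataFrame,
    output: str | Path | None = None,
) -> pd.DataFrame:
    """Tabulate the distinct raw entries of each column, in first-appearance order.

    Useful for spotting typos before validation.  The output frame has one
    column per input column, padded with ``""`` to a rectangle; optionally
    exported to XLSX or CSV.
    """
    df = load_table(path_or_table)
    uniques = {c: list(dict.fromkeys(df[c][df[c] != ""])) for c in df.columns}
    depth = max((len(v) for v in uniques.values()), default=0)
    view = pd.DataFrame(
        {c: v + [""] * (depth - len(v)) for c, v in uniques.items()}
    )
    if output is not None:
        write_table(view, output)
    return view


# ---------------------------------------------------------------------------
# Bundle

#: Which components each workflow step requires.
_STEP_REQUIREMENTS: dict[str, tuple[str, ...]] = {
    "qc_screening": ("results", "accuracy", "frecom"),
    "qc_reporting": ("results", "accuracy", "frecom"),
    "analysis": ("results", "accuracy"),
    "wqx_formatting": ("results", "accuracy", "sites", "wqx"),
}

_COMPONENT_LABEL = {
    "results": "results",
    "accuracy": "DQO accuracy",
    "frecom": "DQO frequency and completeness",
    "sites": "site metadata",
    "wqx": "WQX metadata",
}


@dataclass
class InputBundle:
    """The validated input tables handed to every downstream step."""

    results: pd.DataFrame
    accuracy: pd.DataFrame
    frecom: pd.DataFrame | None = None
    sites: pd.DataFrame | None = None
    wqx: pd.DataFrame | None = None
    config: dict[str, Any] = field(default_factory=default_config)

    def require(self, step: str) -> None:
        """Raise :class:`BundleError` if a component needed by *step* is absent."""
        needed = _STEP_REQUIREMENTS[step]
        for comp in needed:
            if getattr(self, comp) is None:
                raise BundleError(
                    f"workflow step {step!r} requires the "
                    f"{_COMPONENT_LABEL[comp]} file, which is not in the bundle"
                )

    @property
    def rules(self) -> dict[str, list[AccuracyRule]]:
        return parse_accuracy_rules(self.accuracy, self.config)


def bundle(
    results: pd.DataFrame,
    accuracy: pd.DataFrame,
    frecom: pd.DataFrame | None = None,
    sites: pd.DataFrame | None = None,
    wqx: pd.DataFrame | None = None,
    config: dict[str, Any] | None = None,
) -> InputBundle:
    """Assemble previously validated tables into an :class:`InputBundle`."""
    return InputBundle(
        results=results,
        accuracy=accuracy,
        frecom=frecom,
        sites=sites,
        wqx=wqx,
        config=config or default_config(),
    )


def read_bundle(
    results_path: str | Path,
    accuracy_path: str | Path,
    frecom_path: str | Path | None = None,
    sites_path: str | Path | None = None,
    wqx_path: str | Path | None = None,
    config: dict[str, Any] | None = None,
    strict: bool = False,
) -> InputBundle:
    """Read and validate all provided input files into a bundle."""
    cfg = config or default_config()
    res, _ = read_results(results_path, cfg, strict=strict)
    acc = read_accuracy(accuracy_path, cfg)
    frecom = read_frecom(frecom_path, cfg) if frecom_path else None
    sites = read_sites(sites_path, cfg) if sites_path else None
    wqx = read_wqx(wqx_path, cfg) if wqx_path else None
    return InputBundle(res, acc, frecom, sites, wqx, cfg)
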