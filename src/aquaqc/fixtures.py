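"""Deterministic synthetic monitoring bundles for testing and demonstration.

The generator emulates a season of discrete surface-water monitoring: a
May-September sampling calendar over a handful of stations, eight common
parameters (field measurements and lab concentrations, one log-distributed),
regular samples interleaved with QC activities (blanks, duplicates, spikes,
calibration checks), censoring tokens, and injected anomalies.  Everything is
a deterministic function of ``(spec, seed)``, and every injected anomaly is
recorded in a ground-truth sidecar so downstream modules can be checked for
exact recovery.

Generated bundles pass the full fifteen-check validation suite by
construction.  Regular values are drawn from narrow uniform distributions
(lognormal-uniform on log10 for log-flagged parameters): with the 1.5 x IQR
whisker rule, a narrow uniform bulk essentially never produces spurious
flags, so an injected extreme value is the unique outlier in its group and
the sidecar is an exact oracle.

``table4_blank_bundle`` is a separate canned fixture reproducing a published
worked example of field-blank evaluation (seven ammonia blanks below
detection at a 0.1 mg/l threshold; eleven total-phosphorus blanks at a
0.01 mg/l threshold with a single at-threshold miss).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .config import RESULTS_COLUMNS, default_config
from .tabular_io import (
    InputBundle,
    read_accuracy,
    read_frecom,
    read_results,
    read_sites,
    read_wqx,
    write_table,
)

__all__ = [
    "ParameterSpec",
    "FixtureSpec",
    "generate_bundle",
    "corrupt_bundle",
    "write_bundle",
    "table4_blank_bundle",
]


@dataclass(frozen=True)
class ParameterSpec:
    """Distribution and DQO settings for one synthetic parameter."""

    name: str
    unit: str
    kind: str  # "field" | "lab"
    center: float  # distribution center (median for log parameters)
    spread: float  # half-width of the uniform bulk (log10 units if log)
    log: bool = False
    mdl: float | None = None
    uql: float | None = None
    decimals: int = 2
    # DQO criterion strings (empty = no check of that type)
    field_dup: str = "<= 30%"
    lab_dup: str = ""
    field_blank: str = ""
    lab_blank: str = ""
    spike: str = ""


def _default_parameters() -> tuple[ParameterSpec, ...]:
    return (
        ParameterSpec(
            "DO", "mg/l", "field", 8.0, 1.2, decimals=1, spike="<= 10%"
        ),
        ParameterSpec(
            "Water Temp", "deg C", "field", 20.0, 3.0, decimals=1, spike="<= 10%"
        ),
        ParameterSpec(
            "pH", "s.u.", "field", 7.2, 0.4, decimals=1,
            field_dup="<= 0.5", spike="<= 5%",
        ),
        ParameterSpec(
            "Sp Conductance", "uS/cm", "field", 450.0, 60.0, decimals=0, mdl=1.0,
            lab_blank="< 10", spike="<= 10%",
        ),
        ParameterSpec(
            "Ammonia", "mg/l", "lab", 0.4, 0.15, mdl=0.1, uql=5.0, decimals=2,
            lab_dup="<= 20%", field_blank="< 0.1", lab_blank="< 0.1", spike="<= 15%",
        ),
        ParameterSpec(
            "TP", "mg/l", "lab", 0.08, 0.03, mdl=0.01, uql=1.0, decimals=3,
            lab_dup="<= 20%", field_blank="< 0.01", lab_blank="< 0.01", spike="<= 15%",
        ),
        ParameterSpec(
            "Nitrate", "mg/l", "lab", 1.2, 0.35, mdl=0.05, uql=10.0, decimals=2,
            lab_dup="<= 20%", field_blank="< 0.05", lab_blank="< 0.05", spike="<= 15%",
        ),
        ParameterSpec(
            "E.coli", "MPN/100ml", "lab", 120.0, 0.35, log=True, mdl=10.0,
            uql=2400.0, decimals=0,
            field_dup="<= 30% log", lab_dup="<= 30%", field_blank="< 10",
        ),
    )


@dataclass
class FixtureSpec:
    """Study conditions for one synthetic bundle."""

    seed: int = 42
    n_sites: int = 6
    year: int = 2022
    start_month: int = 5
    end_month: int = 9
    sampling_interval_days: int = 14
    parameters: tuple[ParameterSpec, ...] = field(default_factory=_default_parameters)
    field_dup_rate: float = 0.12  # fraction of regular rows carrying a paired value
    lab_qc_per_event: int = 1  # blanks/duplicates/spikes per lab parameter per event
    censored_rate: float = 0.03  # fraction of regular lab rows set to BDL
    # injected anomalies: parameter -> number of extreme values (one per month group)
    outlier_injections: dict[str, int] = field(default_factory=lambda: {"DO": 2})
    outlier_magnitude: float = 3.0  # injected value = bulk upper bound * magnitude
    outlier_group: str = "month"  # grouping under which the sidecar is exact
    # injected QC misses: (parameter, check column) -> count
    qc_misses: dict[tuple[str, str], int] = field(
        default_factory=lambda: {
            ("Ammonia", "Field Duplicate"): 1,
            ("TP", "Field Blank"): 1,
            ("Ammonia", "Lab Blank"): 1,
        }
    )
    required_frequency_pct: float = 10.0
    required_completeness_pct: float = 85.0

    def __post_init__(self) -> None:
        for rate in (self.field_dup_rate, self.censored_rate):
            if not 0 <= rate <= 1:
                raise ValueError(f"rate {rate} outside [0, 1]")


# ---------------------------------------------------------------------------
# Value generation helpers


def _draw(rng: np.random.Generator, p: ParameterSpec, n: int) -> np.ndarray:
    """Regular values: uniform bulk, on log10 scale for log parameters."""
    if p.log:
        lo, hi = math.log10(p.center) - p.spread, math.log10(p.center) + p.spread
        return 10 ** rng.uniform(lo, hi, n)
    lo = max(p.center - p.spread, 0.0)
    return rng.uniform(lo, p.center + p.spread, n)


def _fmt(value: float, p: ParameterSpec) -> str:
    s = f"{value:.{p.decimals}f}"
    return s if float(s) != 0 or value == 0 else f"{value:.{p.decimals + 2}f}"


def _fixture_group_label(row: dict[str, str], group: str) -> str:
    date = row["Activity Start Date"]
    if group == "month":
        return date[:7]
    if group == "year":
        return date[:4]
    if group == "week":
        return pd.Timestamp(date).strftime("%G-%V")
    if group == "site":
        return row["Monitoring Location ID"]
    raise ValueError(f"unknown outlier group {group!r}")


def _regularize_groups(
    rows: list[dict[str, str]],
    idxs: list[int],
    p: ParameterSpec,
    group: str,
    frozen: set[int] | None = None,
    max_passes: int = 25,
) -> None:
    """Remove natural 1.5*IQR flags from a parameter's bulk, in place.

    Iteratively moves any point outside its group's whisker bounds (on the
    parameter's screening scale) to the group median, leaving *frozen* rows
    (the injected extremes) untouched.  Censored rows that would flag are
    un-censored to the median.  Converges because each pass strictly shrinks
    the spread of the movable points in offending groups.
    """
    frozen = frozen or set()
    from .outlier_screen import MIN_GROUP_SIZE, iqr_bounds

    def numeric(i: int) -> float:
        v = rows[i]["Result Value"]
        if v == "BDL":
            return (p.mdl or 0.0) / 2.0
        if v == "AQL":
            return p.uql if p.uql is not None else float("nan")
        return float(v)

    groups: dict[str, list[int]] = {}
    for i in idxs:
        groups.setdefault(_fixture_group_label(rows[i], group), []).append(i)
    for _ in range(max_passes):
        changed = False
        for gi in groups.values():
            if len(gi) < MIN_GROUP_SIZE:
                continue
            vals = np.array([numeric(i) for i in gi], dtype=float)
            screen = np.log10(vals) if p.log else vals
            lo, hi = iqr_bounds(screen)
            med = float(np.median(vals))
            for i, s in zip(gi, screen):
                if (s < lo or s > hi) and i not in frozen:
                    rows[i]["Result Value"] = _fmt(med, p)
                    changed = True
        if not changed:
            return
    raise RuntimeError("could not regularize fixture groups; spec likely degenerate")


def _sampling_dates(spec: FixtureSpec) -> list[str]:
    start = pd.Timestamp(spec.year, spec.start_month, 1)
    end = pd.Timestamp(spec.year, spec.end_month, 28)
    dates = pd.date_range(start, end, freq=f"{spec.sampling_interval_days}D")
    return [d.strftime("%Y-%m-%d") for d in dates]


# ---------------------------------------------------------------------------
# Bundle generation


def generate_bundle(
    spec: FixtureSpec | None = None,
) -> tuple[InputBundle, dict[str, Any]]:
    """Generate a validated five-table bundle plus its ground-truth sidecar.

    The sidecar records every injected anomaly: outliers (site, date,
    parameter, value), QC miss counts per parameter and check type, QC record
    counts, and the regular/qualified record counts behind frequency and
    completeness.  All generated tables re-pass their own read checks before
    being returned.
    """
    spec = spec or FixtureSpec()
    rng = np.random.default_rng(spec.seed)
    cfg = default_config()
    params = {p.name: p for p in spec.parameters}
    dates = _sampling_dates(spec)
    site_ids = [f"SYN-{i + 1:03d}" for i in range(spec.n_sites)]

    sidecar: dict[str, Any] = {
        "seed": spec.seed,
        "outliers": [],
        "qc_misses": {},
        "qc_counts": {},
        "regular_counts": {},
        "qualified_counts": {},
    }

    rows: list[dict[str, str]] = []

    def add_row(**kw: str) -> None:
        base = {c: "" for c in RESULTS_COLUMNS}
        base.update(kw)
        rows.append(base)

    # --- regular samples -------------------------------------------------
    regular_rows_by_param: dict[str, list[int]] = {p: [] for p in params}
    for date_i, date in enumerate(dates):
        for site_i, site in enumerate(site_ids):
            time = f"{6 + site_i % 4:02d}:{(15 * date_i) % 60:02d}"
            for p in spec.parameters:
                value = _draw(rng, p, 1)[0]
                activity = "Field Msr/Obs" if p.kind == "field" else "Sample-Routine"
                regular_rows_by_param[p.name].append(len(rows))
                add_row(**{
                    "Monitoring Location ID": site,
                    "Activity Type": activity,
                    "Activity Start Date": date,
                    "Activity Start Time": time,
                    "Activity Depth/Height Measure": "0.5",
                    "Activity Depth/Height Unit": "m",
                    "Activity Relative Depth Name": "Surface",
                    "Characteristic Name": p.name,
                    "Result Value": _fmt(value, p),
                    "Result Unit": p.unit,
                    "Result Attribute": "DRY" if rng.random() < 0.7 else "WET",
                })

    # --- censoring: set the requested fraction of lab rows to BDL --------
    for p in spec.parameters:
        if p.kind != "lab" or p.mdl is None or spec.censored_rate == 0:
            continue
        idxs = regular_rows_by_param[p.name]
        n_censor = int(round(spec.censored_rate * len(idxs)))
        # censor the lowest values so the substitution is physically sensible
        ordered = sorted(idxs, key=lambda i: float(rows[i]["Result Value"]))
        for i in ordered[:n_censor]:
            rows[i]["Result Value"] = "BDL"

    # --- injected outliers (one per month group, never in a censored row) -
    injected_idx: dict[str, set[int]] = {p: set() for p in spec.outlier_injections}
    for pname, count in spec.outlier_injections.items():
        p = params[pname]
        idxs = [i for i in regular_rows_by_param[pname] if rows[i]["Result Value"] != "BDL"]
        months = sorted({rows[i]["Activity Start Date"][:7] for i in idxs})
        chosen_months = [months[int(k)] for k in
                         np.linspace(0, len(months) - 1, num=count)]
        for month in chosen_months:
            month_rows = [i for i in idxs if rows[i]["Activity Start Date"].startswith(month)]
            i = int(rng.choice(month_rows))
            if p.log:
                extreme = (10 ** (math.log10(p.center) + p.spread)) * 10 ** spec.outlier_magnitude
            else:
                extreme = (p.center + p.spread) * spec.outlier_magnitude
            rows[i]["Result Value"] = _fmt(extreme, p)
            injected_idx[pname].add(i)
            sidecar["outliers"].append(
                {
                    "Monitoring Location ID": rows[i]["Monitoring Location ID"],
                    "Activity Start Date": rows[i]["Activity Start Date"],
                    "Activity Start Time": rows[i]["Activity Start Time"],
                    "Characteristic Name": pname,
                    "Result Value": rows[i]["Result Value"],
                    "Result Unit": p.unit,
                }
            )

    # --- make the sidecar exact: pull any naturally flagged bulk point to
    # its group median so the injected extremes are the only flags under the
    # recorded grouping (injected rows held fixed)
    for pname in spec.outlier_injections:
        _regularize_groups(
            rows,
            regular_rows_by_param[pname],
            params[pname],
            spec.outlier_group,
            frozen=injected_idx[pname],
        )

    # --- QC records -------------------------------------------------------
    def record_miss(pname: str, check: str, n: int = 1) -> None:
        sidecar["qc_misses"].setdefault(pname, {})
        sidecar["qc_misses"][pname][check] = sidecar["qc_misses"][pname].get(check, 0) + n

    def count_qc(pname: str, check: str, n: int = 1) -> None:
        sidecar["qc_counts"].setdefault(pname, {})
        sidecar["qc_counts"][pname][check] = sidecar["qc_counts"][pname].get(check, 0) + n

    miss_budget = dict(spec.qc_misses)

    # field duplicates: paired value in the QC Reference Value column of a
    # regular row (the row becomes a qualified sample)
    for p in spec.parameters:
        if not p.field_dup:
            continue
        idxs = [i for i in regular_rows_by_param[p.name] if rows[i]["Result Value"] != "BDL"]
        # avoid pairing the injected outliers: their duplicate would inherit
        # the anomaly and confound the sidecar
        outlier_keys = {
            (o["Monitoring Location ID"], o["Activity Start Date"], o["Characteristic Name"])
            for o in sidecar["outliers"]
        }
        idxs = [
            i for i in idxs
            if (rows[i]["Monitoring Location ID"], rows[i]["Activity Start Date"], p.name)
            not in outlier_keys
        ]
        n_dup = max(2, int(math.ceil(spec.field_dup_rate * len(regular_rows_by_param[p.name]))))
        chosen = sorted(rng.choice(idxs, size=min(n_dup, len(idxs)), replace=False))
        n_miss = miss_budget.pop((p.name, "Field Duplicate"), 0)
        absolute = "%" not in p.field_dup
        for j, i in enumerate(chosen):
            v = float(rows[i]["Result Value"])
            if j < n_miss:
                ref = v + 1.6 * float(p.field_dup.split()[-1]) if absolute else v * 2.2
                record_miss(p.name, "Field Duplicates")
            else:
                ref = v + 0.2 * float(p.field_dup.split()[-1]) if absolute else v * 1.05
            rows[i]["QC Reference Value"] = _fmt(ref, p)
            count_qc(p.name, "Field Duplicates")

    # lab QC rows: blanks, duplicates, spikes per sampling event
    for date_i, date in enumerate(dates):
        time = f"10:{(7 * date_i) % 60:02d}"
        for p in spec.parameters:
            threshold = None
            if p.field_blank:
                threshold = float(p.field_blank.split()[-1])
                n_miss = miss_budget.pop((p.name, "Field Blank"), 0) if date_i == 0 else 0
                for k in range(spec.lab_qc_per_event):
                    miss = k < n_miss
                    add_row(**{
                        "Activity Type": "Quality Control Sample-Field Blank",
                        "Activity Start Date": date,
                        "Activity Start Time": time,
                        "Characteristic Name": p.name,
                        "Result Value": _fmt(threshold, p) if miss else "BDL",
                        "Result Unit": p.unit,
                    })
                    if miss:
                        record_miss(p.name, "Field Blanks")
                    count_qc(p.name, "Field Blanks")
            if p.lab_blank:
                threshold = float(p.lab_blank.split()[-1])
                n_miss = miss_budget.pop((p.name, "Lab Blank"), 0) if date_i == 0 else 0
                for k in range(spec.lab_qc_per_event):
                    miss = k < n_miss
                    add_row(**{
                        "Activity Type": "Quality Control Sample-Lab Blank",
                        "Activity Start Date": date,
                        "Activity Start Time": time,
                        "Characteristic Name": p.name,
                        "Result Value": _fmt(threshold, p) if miss else "BDL",
                        "Result Unit": p.unit,
                    })
                    if miss:
                        record_miss(p.name, "Lab Blanks")
                    count_qc(p.name, "Lab Blanks")
            if p.lab_dup:
                n_miss = miss_budget.pop((p.name, "Lab Duplicate"), 0) if date_i == 0 else 0
                for k in range(spec.lab_qc_per_event):
                    v = _draw(rng, p, 1)[0]
                    miss = k < n_miss
                    ref = v * (2.2 if miss else 1.04)
                    add_row(**{
                        "Activity Type": "Quality Control Sample-Lab Duplicate",
                        "Activity Start Date": date,
                        "Activity Start Time": time,
                        "Characteristic Name": p.name,
                        "Result Value": _fmt(v, p),
                        "QC Reference Value": _fmt(ref, p),
                        "Result Unit": p.unit,
                    })
                    if miss:
                        record_miss(p.name, "Lab Duplicates")
                    count_qc(p.name, "Lab Duplicates")
            if p.spike:
                n_miss = miss_budget.pop((p.name, "Spike/Check Accuracy"), 0) if date_i == 0 else 0
                activity = (
                    "Quality Control-Calibration Check"
                    if p.kind == "field"
                    else "Quality Control Sample-Lab Spike"
                )
                for k in range(spec.lab_qc_per_event):
                    known = p.center
                    miss = k < n_miss
                    measured = known * (1.5 if miss else 1.02)
                    add_row(**{
                        "Activity Type": activity,
                        "Activity Start Date": date,
                        "Activity Start Time": time,
                        "Characteristic Name": p.name,
                        "Result Value": _fmt(measured, p),
                        "QC Reference Value": _fmt(known, p),
                        "Result Unit": p.unit,
                    })
                    if miss:
                        record_miss(p.name, "Lab Spikes / Instrument Checks")
                    count_qc(p.name, "Lab Spikes / Instrument Checks")

    if miss_budget:
        unused = ", ".join(f"{p}/{c}" for p, c in miss_budget)
        raise ValueError(f"infeasible spec: no QC records to host injected miss(es) for {unused}")

    results = pd.DataFrame(rows, columns=list(RESULTS_COLUMNS))

    # frequency / completeness ground truth
    for p in spec.parameters:
        idxs = regular_rows_by_param[p.name]
        qualified = sum(1 for i in idxs if rows[i]["QC Reference Value"] != "")
        sidecar["regular_counts"][p.name] = len(idxs)
        sidecar["qualified_counts"][p.name] = qualified

    # --- DQO tables -------------------------------------------------------
    acc = pd.DataFrame(
        [
            {
                "Parameter": p.name,
                "MDL": "" if p.mdl is None else f"{p.mdl:g}",
                "UQL": "" if p.uql is None else f"{p.uql:g}",
                "Value Range": "all",
                "Field Duplicate": p.field_dup,
                "Lab Duplicate": p.lab_dup,
                "Field Blank": p.field_blank,
                "Lab Blank": p.lab_blank,
                "Spike/Check Accuracy": p.spike,
            }
            for p in spec.parameters
        ]
    )
    freq = f"{spec.required_frequency_pct:g}"
    frecom = pd.DataFrame(
        [
            {
                "Parameter": p.name,
                "Field Duplicate": freq if p.field_dup else "",
                "Lab Duplicate": freq if p.lab_dup else "",
                "Field Blank": freq if p.field_blank else "",
                "Lab Blank": freq if p.lab_blank else "",
                "Spike/Check Accuracy": freq if p.spike else "",
                "% Completeness": f"{spec.required_completeness_pct:g}",
            }
            for p in spec.parameters
        ]
    )

    # --- sites & WQX metadata --------------------------------------------
    rng_sites = np.random.default_rng(spec.seed + 1)
    sites = pd.DataFrame(
        [
            {
                "Monitoring Location ID": site,
                "Monitoring Location Latitude": f"{42.3 + rng_sites.uniform(-0.1, 0.1):.4f}",
                "Monitoring Location Longitude": f"{-71.5 + rng_sites.uniform(-0.1, 0.1):.4f}",
                "Location Group": "Mainstem" if i < spec.n_sites // 2 else "Tributary",
            }
            for i, site in enumerate(site_ids)
        ]
    )
    wqx = pd.DataFrame(
        [
            {
                "Parameter": p.name,
                "Result Sample Fraction": "Total" if p.kind == "lab" else "",
                "Result Analytical Method ID": f"SYN-{p.name[:3].upper()}",
                "Result Analytical Method Context": "SYNTHETIC-LAB",
                "Method Speciation": "as P" if p.name == "TP" else "",
            }
            for p in spec.parameters
        ]
    )

    # self-consistency: everything must re-pass its own checks
    res_checked, outcomes = read_results(results, cfg)
    if not all(o.status == "ok" for o in outcomes):
        raise RuntimeError("generated results failed its own validation suite")
    bundle = InputBundle(
        results=res_checked,
        accuracy=read_accuracy(acc, cfg),
        frecom=read_frecom(frecom, cfg),
        sites=read_sites(sites, cfg),
        wqx=read_wqx(wqx, cfg),
        config=cfg,
    )
    return bundle, sidecar


def write_bundle(
    bundle: InputBundle,
    sidecar: dict[str, Any],
    output_dir: str | Path,
    fmt: str = "csv",
) -> dict[str, Path]:
    """Write the five tables plus the sidecar to *output_dir*; returns paths."""
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    ext = ".xlsx" if fmt == "xlsx" else ".csv"
    paths = {}
    for name, df in (
        ("results", bundle.results),
        ("accuracy", bundle.accuracy),
        ("frecom", bundle.frecom),
        ("sites", bundle.sites),
        ("wqx", bundle.wqx),
    ):
        paths[name] = write_table(df, output_dir / f"{name}{ext}")
    sidecar_path = output_dir / "ground_truth.json"
    sidecar_path.write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    paths["sidecar"] = sidecar_path
    return paths


def corrupt_bundle(
    results: pd.DataFrame,
    mutations: Sequence[tuple[int, str, str] | tuple[str, str]],
) -> tuple[pd.DataFrame, list[str]]:
    """Apply targeted corruptions to a results table for validator testing.

    Mutations are ``(data_row_1based, column, new_value)`` cell overwrites or
    ``("drop_column", column)`` deletions.  Returns the mutated copy and a
    log of the applied mutations.
    """
    out = results.copy()
    log: list[str] = []
    for m in mutations:
        if m[0] == "drop_column":
            _, col = m
            if col not in out.columns:
                raise IndexError(f"no column {col!r} to drop")
            out = out.drop(columns=[col])
            log.append(f"dropped column {col}")
        else:
            row, col, value = m
            if not 1 <= row <= len(out):
                raise IndexError(f"row {row} outside 1..{len(out)}")
            if col not in out.columns:
                raise IndexError(f"no column {col!r}")
            out.iloc[row - 1, out.columns.get_loc(col)] = value
            log.append(f"set row {row}, {col} = {value!r}")
    return out, log


# ---------------------------------------------------------------------------
# Canned worked example: field-blank evaluation


def table4_blank_bundle() -> InputBundle:
    """Canned bundle reproducing a published field-blank worked example.

    Eighteen field-blank records: seven ammonia blanks, all below detection
    against a 0.1 mg/l threshold, and eleven total-phosphorus blanks against
    a 0.01 mg/l threshold of which exactly one (a 0.01 mg/l reading equal to
    the threshold) is a miss under the strict ``<`` criterion.  Expected
    acceptance: ammonia 100%, TP 91%.
    """
    amm_dates = [
        "2022-05-15", "2022-06-12", "2022-07-17", "2022-07-17",
        "2022-08-14", "2022-08-14", "2022-09-11",
    ]
    tp_dates = [
        "2022-05-15", "2022-05-15", "2022-06-12", "2022-06-12",
        "2022-07-17", "2022-07-17", "2022-07-17",
        "2022-08-14", "2022-08-14", "2022-09-11", "2022-09-11",
    ]
    tp_values = ["BDL"] * 6 + ["0.01"] + ["BDL"] * 4  # the 3rd 07-17 blank misses

    rows = []
    for date in amm_dates:
        rows.append(("Ammonia", date, "BDL"))
    for date, value in zip(tp_dates, tp_values):
        rows.append(("TP", date, value))

    results = pd.DataFrame(
        [
            {
                "Monitoring Location ID": "",
                "Activity Type": "Quality Control Sample-Field Blank",
                "Activity Start Date": date,
                "Activity Start Time": "07:00",
                "Activity Depth/Height Measure": "",
                "Activity Depth/Height Unit": "",
                "Activity Relative Depth Name": "",
                "Characteristic Name": param,
                "Result Value": value,
                "QC Reference Value": "",
                "Result Unit": "mg/l",
                "Result Attribute": "",
            }
            for param, date, value in rows
        ],
        columns=list(RESULTS_COLUMNS),
    )
    accuracy = pd.DataFrame(
        [
            {
                "Parameter": "Ammonia", "MDL": "0.1", "UQL": "", "Value Range": "all",
                "Field Duplicate": "<= 30%", "Lab Duplicate": "<= 20%",
                "Field Blank": "< 0.1", "Lab Blank": "< 0.1",
                "Spike/Check Accuracy": "<= 15%",
            },
            {
                "Parameter": "TP", "MDL": "0.01", "UQL": "", "Value Range": "all",
                "Field Duplicate": "<= 30%", "Lab Duplicate": "<= 20%",
                "Field Blank": "< 0.01", "Lab Blank": "< 0.01",
                "Spike/Check Accuracy": "<= 15%",
            },
        ]
    )
    frecom = pd.DataFrame(
        [
            {
                "Parameter": p, "Field Duplicate": "10", "Lab Duplicate": "10",
                "Field Blank": "10", "Lab Blank": "10",
                "Spike/Check Accuracy": "10", "% Completeness": "90",
            }
            for p in ("Ammonia", "TP")
        ]
    )
    cfg = default_config()
    res_checked, outcomes = read_results(results, cfg)
    if not all(o.status == "ok" for o in outcomes):
        raise RuntimeError("canned blank bundle failed validation")
    return InputBundle(
        results=res_checked,
        accuracy=read_accuracy(accuracy, cfg),
        frecom=read_frecom(frecom, cfg),
        config=cfg,
    )
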