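"""Three-sheet WQX submission workbook builder.

The USEPA Water Quality Exchange accepts physical/chemical results as an
Excel workbook with sheets named ``Project``, ``Locations``, and ``Results``.
This module populates all three from the input bundle with as much content
as the inputs provide; required columns are always present even when blank,
and row-level verification before upload stays with the user.

Conventions applied:

* censored results export a blank ``Result Value`` plus a detection-condition
  entry (``Not Detected`` for BDL, ``Present Above Quantification Limit`` for
  AQL) and the corresponding detection/quantitation limit from the accuracy
  DQOs — no fabricated numbers;
* a same-row duplicate pair expands into two Results rows connected by the
  paired activity types (e.g. ``Quality Control Sample-Lab Duplicate 1`` /
  ``... 2``); the expansion factor is logged;
* time zone and sample-collection defaults come from the configuration, not
  from hard-coded regional values.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Any

from openpyxl import Workbook

from .criteria import is_censored
from .tabular_io import InputBundle, select_rule

logger = logging.getLogger(__name__)

__all__ = ["build_wqx_workbook", "SHEET_NAMES"]

SHEET_NAMES = ("Project", "Locations", "Results")

PROJECT_COLUMNS = ("Project ID", "Project Name", "Project Description")

LOCATION_COLUMNS = (
    "Monitoring Location ID",
    "Monitoring Location Name",
    "Monitoring Location Latitude",
    "Monitoring Location Longitude",
    "Monitoring Location Source Map Scale",
    "Monitoring Location Horizontal Collection Method",
    "Monitoring Location Horizontal Coordinate Reference System",
    "Monitoring Location Type",
)

_DETECTION_CONDITION = {
    "BDL": "Not Detected",
    "AQL": "Present Above Quantification Limit",
}

_PAIRED_ACTIVITY = {
    "Quality Control Sample-Lab Duplicate": (
        "Quality Control Sample-Lab Duplicate 1",
        "Quality Control Sample-Lab Duplicate 2",
    ),
    "Field Msr/Obs": (
        "Field Msr/Obs",
        "Quality Control Field Replicate Msr/Obs",
    ),
    "Sample-Routine": (
        "Sample-Routine",
        "Quality Control Field Replicate Portable Data Logger",
    ),
}


def _write_sheet(ws: Any, columns: tuple[str, ...] | list[str], rows: list[dict]) -> None:
    ws.append(list(columns))
    for row in rows:
        ws.append([str(row.get(c, "")) if row.get(c, "") != "" else None for c in columns])
    for col in ws.iter_cols():
        for cell in col:
            cell.number_format = "@"


def build_wqx_workbook(
    bundle: InputBundle,
    output_dir: str | Path,
    config: dict[str, Any] | None = None,
    filename: str = "wqxtab.xlsx",
) -> Path:
    """Build the WQX submission workbook from a full bundle.

    Requires the results, accuracy, sites, and WQX metadata components.
    Returns the workbook path after printing a success message.
    """
    bundle.require("wqx_formatting")
    cfg = config or bundle.config
    defaults = cfg["wqx_defaults"]
    columns = list(cfg["wqx_results_columns"])
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)

    # sites referenced by the results must appear on the Locations sheet
    site_ids = set(bundle.sites["Monitoring Location ID"])
    used = {s for s in bundle.results["Monitoring Location ID"] if s.strip()}
    orphans = sorted(used - site_ids)
    if orphans:
        raise ValueError(
            "site(s) referenced in results but missing from the site metadata: "
            + ", ".join(orphans)
        )

    wqx_meta = bundle.wqx.set_index("Parameter") if bundle.wqx is not None else None
    rules = bundle.rules

    def meta_for(parameter: str, column: str) -> str:
        if wqx_meta is None or parameter not in wqx_meta.index:
            return ""
        return str(wqx_meta.loc[parameter].get(column, "")) if column in wqx_meta.columns else ""

    result_rows: list[dict] = []
    n_expanded = 0
    for i, row in bundle.results.iterrows():
        p = row["Characteristic Name"]
        base = {
            "Project ID": defaults["project_id"],
            "Monitoring Location ID": row["Monitoring Location ID"],
            "Activity ID": f"{defaults['project_id']}-{i + 1}",
            "Activity Type": row["Activity Type"],
            "Activity Media Name": defaults["activity_media_name"],
            "Activity Start Date": row["Activity Start Date"],
            "Activity Start Time": row["Activity Start Time"],
            "Activity Start Time Zone": defaults["time_zone"],
            "Activity Depth/Height Measure": row["Activity Depth/Height Measure"],
            "Activity Depth/Height Unit": row["Activity Depth/Height Unit"],
            "Activity Relative Depth Name": row["Activity Relative Depth Name"],
            "Sample Collection Method ID": defaults["sample_collection_method_id"],
            "Sample Collection Method Context": defaults["sample_collection_method_context"],
            "Sample Collection Equipment Name": defaults["sample_collection_equipment_name"],
            "Characteristic Name": p,
            "Method Speciation": meta_for(p, "Method Speciation"),
            "Result Unit": row["Result Unit"],
            "Result Status ID": defaults["result_status"],
            "Result Value Type": defaults["result_value_type"],
            "Result Sample Fraction": meta_for(p, "Result Sample Fraction"),
            "Result Analytical Method ID": meta_for(p, "Result Analytical Method ID"),
            "Result Analytical Method Context": meta_for(p, "Result Analytical Method Context"),
        }

        def with_value(value: str, activity_type: str | None = None, suffix: str = "") -> dict:
            out = dict(base)
            if activity_type is not None:
                out["Activity Type"] = activity_type
            if suffix:
                out["Activity ID"] = out["Activity ID"] + suffix
            v = value.strip()
            if is_censored(v):
                token = v.upper()
                out["Result Value"] = ""
                out["Result Detection Condition"] = _DETECTION_CONDITION[token]
                rule = select_rule(rules.get(p, []), None)
                if rule is not None:
                    if token == "BDL" and rule.mdl is not None:
                        out["Result Detection/Quantitation Limit Type"] = "Method Detection Level"
                        out["Result Detection/Quantitation Limit Measure"] = f"{rule.mdl:g}"
                        out["Result Detection/Quantitation Limit Unit"] = row["Result Unit"]
                    elif token == "AQL" and rule.uql is not None:
                        out["Result Detection/Quantitation Limit Type"] = "Upper Quantitation Limit"
                        out["Result Detection/Quantitation Limit Measure"] = f"{rule.uql:g}"
                        out["Result Detection/Quantitation Limit Unit"] = row["Result Unit"]
            else:
                out["Result Value"] = v
                out["Result Detection Condition"] = ""
            return out

        ref = row["QC Reference Value"].strip()
        at = row["Activity Type"]
        if ref and at in _PAIRED_ACTIVITY:
            first, second = _PAIRED_ACTIVITY[at]
            result_rows.append(with_value(row["Result Value"], first, "-a"))
            result_rows.append(with_value(ref, second, "-b"))
            n_expanded += 1
        else:
            result_rows.append(with_value(row["Result Value"]))

    if n_expanded:
        logger.info(
            "expanded %d same-row duplicate pair(s) into paired Results rows "
            "(%d results rows from %d records)",
            n_expanded,
            len(result_rows),
            len(bundle.results),
        )

    wb = Workbook()
    ws = wb.active
    ws.title = "Project"
    _write_sheet(
        ws,
        PROJECT_COLUMNS,
        [
            {
                "Project ID": defaults["project_id"],
                "Project Name": defaults.get("project_name", defaults["project_id"]),
                "Project Description": defaults.get(
                    "project_description", "Discrete water quality monitoring"
                ),
            }
        ],
    )

    loc_rows = []
    for _, s in bundle.sites.iterrows():
        loc_rows.append(
            {
                "Monitoring Location ID": s["Monitoring Location ID"],
                "Monitoring Location Name": s["Monitoring Location ID"],
                "Monitoring Location Latitude": s["Monitoring Location Latitude"],
                "Monitoring Location Longitude": s["Monitoring Location Longitude"],
                "Monitoring Location Horizontal Coordinate Reference System": "WGS84",
                "Monitoring Location Type": defaults.get(
                    "monitoring_location_type", "River/Stream"
                ),
            }
        )
    _write_sheet(wb.create_sheet("Locations"), LOCATION_COLUMNS, loc_rows)
    _write_sheet(wb.create_sheet("Results"), columns, result_rows)

    path = output_dir / filename
    wb.save(path)
    print(f"Excel workbook created successfully! File located at {path}")
    return path
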