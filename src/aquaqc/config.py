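"""Editable configuration: controlled vocabularies, parameter dictionary, thresholds.

All vocabularies used by the validators ship as plain data so programs outside
Massachusetts can adapt the tool by editing a YAML file instead of the source.
``load_config`` merges a user YAML over the defaults; every consumer takes a
``config`` mapping so tests can inject variants.
"""

from __future__ import annotations

import copy
from pathlib import Path
from typing import Any, Mapping

import yaml

# WQX-style activity types.  Field duplicates do not get their own activity
# type: the duplicate value rides in the "QC Reference Value" column of a
# routine row, so only blank/lab-duplicate/spike/calibration rows are QC rows.
ACTIVITY_TYPES: tuple[str, ...] = (
    "Field Msr/Obs",
    "Sample-Routine",
    "Quality Control Sample-Field Blank",
    "Quality Control Sample-Lab Blank",
    "Quality Control Sample-Lab Duplicate",
    "Quality Control Sample-Lab Spike",
    "Quality Control-Calibration Check",
)

REGULAR_ACTIVITY_TYPES: tuple[str, ...] = ("Field Msr/Obs", "Sample-Routine")

RELATIVE_DEPTH_NAMES: tuple[str, ...] = (
    "Surface",
    "Bottom",
    "Midwater",
    "Near Bottom",
)

DEPTH_UNITS: tuple[str, ...] = ("m", "ft")

CENSOR_TOKENS: tuple[str, ...] = ("BDL", "AQL")

#: Results-file column order; check 1 requires these names exactly.
RESULTS_COLUMNS: tuple[str, ...] = (
    "Monitoring Location ID",
    "Activity Type",
    "Activity Start Date",
    "Activity Start Time",
    "Activity Depth/Height Measure",
    "Activity Depth/Height Unit",
    "Activity Relative Depth Name",
    "Characteristic Name",
    "Result Value",
    "QC Reference Value",
    "Result Unit",
    "Result Attribute",
)

ACCURACY_COLUMNS: tuple[str, ...] = (
    "Parameter",
    "MDL",
    "UQL",
    "Value Range",
    "Field Duplicate",
    "Lab Duplicate",
    "Field Blank",
    "Lab Blank",
    "Spike/Check Accuracy",
)

FRECOM_COLUMNS: tuple[str, ...] = (
    "Parameter",
    "Field Duplicate",
    "Lab Duplicate",
    "Field Blank",
    "Lab Blank",
    "Spike/Check Accuracy",
    "% Completeness",
)

SITES_COLUMNS: tuple[str, ...] = (
    "Monitoring Location ID",
    "Monitoring Location Latitude",
    "Monitoring Location Longitude",
    "Location Group",
)

#: The five accuracy check types, in report order.  Calibration checks fold
#: into the spike column, giving the familiar five-column QC summary layout.
CHECK_TYPES: tuple[str, ...] = (
    "Field Duplicates",
    "Lab Duplicates",
    "Field Blanks",
    "Lab Blanks",
    "Lab Spikes / Instrument Checks",
)

#: Accuracy-rule column feeding each check type.
CHECK_TYPE_TO_RULE: dict[str, str] = {
    "Field Duplicates": "Field Duplicate",
    "Lab Duplicates": "Lab Duplicate",
    "Field Blanks": "Field Blank",
    "Lab Blanks": "Lab Blank",
    "Lab Spikes / Instrument Checks": "Spike/Check Accuracy",
}

#: Frequency/completeness-rule column per check type (same names minus completeness).
CHECK_TYPE_TO_FRECOM: dict[str, str] = dict(CHECK_TYPE_TO_RULE)

# Parameter dictionary: allowed units per parameter.  Deliberately editable and
# not a fixed-length master list; extend via YAML for other programs.
PARAMETERS: dict[str, dict[str, Any]] = {
    "DO": {"units": ["mg/l"], "log": False},
    "Ammonia": {"units": ["mg/l"], "log": False},
    "TP": {"units": ["mg/l", "ug/l"], "log": False},
    "Nitrate": {"units": ["mg/l"], "log": False},
    "pH": {"units": ["s.u.", "None"], "log": False},
    "Sp Conductance": {"units": ["uS/cm"], "log": False},
    "E.coli": {"units": ["MPN/100ml", "CFU/100ml"], "log": True},
    "Water Temp": {"units": ["deg C", "deg F"], "log": False},
    "Chl a": {"units": ["ug/l", "mg/l"], "log": True},
    "TSS": {"units": ["mg/l"], "log": False},
    "Turbidity": {"units": ["NTU"], "log": False},
    "Enterococcus": {"units": ["MPN/100ml", "CFU/100ml"], "log": True},
    "Salinity": {"units": ["ppt", "psu"], "log": False},
    "TN": {"units": ["mg/l"], "log": False},
}

#: Parameters for which negative result values are physically meaningful.
NEGATIVE_OK_PARAMETERS: tuple[str, ...] = ("Water Temp",)

#: Threshold overlays for plots: parameter -> context -> entries.  Values are
#: editable placeholders for common regulatory/designated-use limits; each entry
#: carries the source string displayed in legends.
THRESHOLDS: dict[str, dict[str, list[dict[str, Any]]]] = {
    "DO": {
        "fresh": [
            {
                "label": "Class A/B warmwater minimum",
                "value": 5.0,
                "unit": "mg/l",
                "source": "State surface water quality standard",
            }
        ],
        "marine": [
            {
                "label": "Class SA/SB minimum",
                "value": 6.0,
                "unit": "mg/l",
                "source": "State surface water quality standard",
            }
        ],
    },
    "E.coli": {
        "fresh": [
            {
                "label": "Primary contact recreation",
                "value": 126.0,
                "unit": "MPN/100ml",
                "source": "USEPA recreational water quality criteria",
            }
        ],
    },
    "TP": {
        "fresh": [
            {
                "label": "Nutrient guidance",
                "value": 0.1,
                "unit": "mg/l",
                "source": "USEPA ecoregional nutrient criteria",
            }
        ],
    },
    "pH": {
        "fresh": [
            {
                "label": "Acceptable range (low)",
                "value": 6.5,
                "unit": "s.u.",
                "source": "State surface water quality standard",
            },
            {
                "label": "Acceptable range (high)",
                "value": 8.3,
                "unit": "s.u.",
                "source": "State surface water quality standard",
            },
        ],
    },
}

#: WQX physical/chemical Results-sheet column set (editable template order).
WQX_RESULTS_COLUMNS: tuple[str, ...] = (
    "Project ID",
    "Monitoring Location ID",
    "Activity ID",
    "Activity Type",
    "Activity Media Name",
    "Activity Start Date",
    "Activity Start Time",
    "Activity Start Time Zone",
    "Activity Depth/Height Measure",
    "Activity Depth/Height Unit",
    "Activity Relative Depth Name",
    "Sample Collection Method ID",
    "Sample Collection Method Context",
    "Sample Collection Equipment Name",
    "Characteristic Name",
    "Method Speciation",
    "Result Detection Condition",
    "Result Value",
    "Result Unit",
    "Result Measure Qualifier",
    "Result Sample Fraction",
    "Result Status ID",
    "Result Value Type",
    "Result Analytical Method ID",
    "Result Analytical Method Context",
    "Result Detection/Quantitation Limit Type",
    "Result Detection/Quantitation Limit Measure",
    "Result Detection/Quantitation Limit Unit",
)

WQX_DEFAULTS: dict[str, str] = {
    "time_zone": "EST",
    "activity_media_name": "Water",
    "project_id": "aquaqc-project",
    "result_status": "Final",
    "result_value_type": "Actual",
    "sample_collection_method_id": "Grab",
    "sample_collection_method_context": "aquaqc",
    "sample_collection_equipment_name": "Water Bottle",
}


def default_config() -> dict[str, Any]:
    """Return a deep copy of the built-in configuration mapping."""
    return copy.deepcopy(
        {
            "activity_types": list(ACTIVITY_TYPES),
            "regular_activity_types": list(REGULAR_ACTIVITY_TYPES),
            "relative_depth_names": list(RELATIVE_DEPTH_NAMES),
            "depth_units": list(DEPTH_UNITS),
            "censor_tokens": list(CENSOR_TOKENS),
            "parameters": PARAMETERS,
            "negative_ok_parameters": list(NEGATIVE_OK_PARAMETERS),
            "thresholds": THRESHOLDS,
            "wqx_results_columns": list(WQX_RESULTS_COLUMNS),
            "wqx_defaults": WQX_DEFAULTS,
            "qualifier_column": None,
            "row_index_offset": 0,  # set 1 for spreadsheet-style addressing
        }
    )


def load_config(path: str | Path | None = None) -> dict[str, Any]:
    """Load configuration, merging a user YAML file over the defaults.

    Top-level keys in the YAML replace the default value wholesale except
    ``parameters`` and ``thresholds``, which merge per parameter.
    """
    cfg = default_config()
    if path is None:
        return cfg
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    for key, value in user.items():
        if key in ("parameters", "thresholds") and isinstance(value, Mapping):
            cfg[key] = {**cfg[key], **value}
        else:
            cfg[key] = value
    return cfg
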