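"""Outlier screening with the 1.5 x IQR rule on grouped observations.

Potential outliers are flagged, never removed: within each group (month,
week, year, or site) a value is flagged when it falls strictly outside
``[Q1 - k*IQR, Q3 + k*IQR]`` with ``k = 1.5`` and quartiles estimated by
linear interpolation between order statistics (the common type-7 rule).
Parameters hinted as log-distributed in the accuracy DQOs are screened on
log10 values, which changes which points are extreme relative to the bulk.

Censored values are first replaced with conventional stand-ins (``BDL`` ->
MDL/2, ``AQL`` -> UQL) from the accuracy rules.  Groups with fewer than four
points are skipped — quartiles are too unstable to call outliers there.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .criteria import is_censored
from .tabular_io import AccuracyRule, InputBundle, select_rule

logger = logging.getLogger(__name__)

__all__ = [
    "OUTLIER_COLUMNS",
    "iqr_bounds",
    "substitute_censored",
    "detect_outliers",
    "batch_outliers",
]

#: Column order of the tabular outlier output.
OUTLIER_COLUMNS: tuple[str, ...] = (
    "Monitoring Location ID",
    "Activity Start Date",
    "Activity Start Time",
    "Characteristic Name",
    "Result Value",
    "Result Unit",
)

MIN_GROUP_SIZE = 4


def iqr_bounds(values: Sequence[float], k: float = 1.5) -> tuple[float, float]:
    """Whisker bounds ``(Q1 - k*IQR, Q3 + k*IQR)`` with type-7 quartiles."""
    arr = np.asarray(values, dtype=float)
    q1, q3 = np.quantile(arr, [0.25, 0.75])  # default linear interpolation
    iqr = q3 - q1
    return q1 - k * iqr, q3 + k * iqr


def substitute_censored(
    values: Sequence[str | float], rule: AccuracyRule | None
) -> tuple[list[float], list[int]]:
    """Replace censoring tokens with numeric stand-ins.

    ``BDL`` becomes half the method detection limit, ``AQL`` the upper
    quantification limit.  Returns the numeric values and the positions kept;
    tokens without a configured limit are excluded with a notice.
    """
    out: list[float] = []
    kept: list[int] = []
    for i, v in enumerate(values):
        if isinstance(v, str) and is_censored(v):
            t = v.strip().upper()
            if rule is None:
                logger.warning("censored value %r with no accuracy rule; excluded", v)
                continue
            sub = rule.mdl / 2.0 if t == "BDL" and rule.mdl is not None else (
                rule.uql if t == "AQL" and rule.uql is not None else None
            )
            if sub is None:
                logger.warning("censored value %r lacks an MDL/UQL; excluded", v)
                continue
            logger.info("substituted %s for censored %s", sub, t)
            out.append(float(sub))
        else:
            out.append(float(v))
        kept.append(i)
    return out, kept


def _group_labels(df: pd.DataFrame, group: str) -> pd.Series:
    dates = pd.to_datetime(df["Activity Start Date"])
    if group == "month":
        return dates.dt.strftime("%b")
    if group == "week":
        return dates.dt.isocalendar().week.astype(int).astype(str)
    if group == "year":
        return dates.dt.year.astype(str)
    if group == "site":
        return df["Monitoring Location ID"]
    raise ValueError(f"unknown group {group!r}: use month, week, year, or site")


def detect_outliers(
    bundle: InputBundle,
    param: str,
    group: str = "month",
    outliers_table: bool = True,
    k: float = 1.5,
    plot_path: str | Path | None = None,
) -> pd.DataFrame:
    """Flag potential outliers for one parameter within x-axis groups.

    Returns the flagged observations with the six tabular-output columns.
    Flags are group-specific, so the set can differ with the grouping choice.
    When *plot_path* is given, a boxplot with flagged points labeled by
    station id is written there.
    """
    res = bundle.results
    regular = set(bundle.config["regular_activity_types"])
    sub = res[
        (res["Characteristic Name"] == param) & res["Activity Type"].isin(regular)
    ].copy()
    if sub.empty:
        raise ValueError(f"parameter {param!r} not present in results")
    rules = bundle.rules.get(param, [])
    rule = select_rule(rules, None) if rules else None
    scale = rule.scale_hint if rule is not None else "linear"

    values, kept = substitute_censored(list(sub["Result Value"]), rule)
    sub = sub.iloc[kept].copy()
    sub["_value"] = values
    if scale == "log":
        pos = sub["_value"] > 0
        if (~pos).any():
            logger.warning(
                "%d non-positive values excluded from log-scale screening of %s",
                int((~pos).sum()),
                param,
            )
        sub = sub[pos].copy()
        sub["_screen"] = np.log10(sub["_value"])
    else:
        sub["_screen"] = sub["_value"]

    sub["_group"] = _group_labels(sub, group)
    flagged_idx: list[int] = []
    for label, grp in sub.groupby("_group", sort=False):
        if len(grp) < MIN_GROUP_SIZE:
            logger.info(
                "group %r has %d < %d points; no outliers flagged",
                label,
                len(grp),
                MIN_GROUP_SIZE,
            )
            continue
        lo, hi = iqr_bounds(grp["_screen"].to_numpy(), k=k)
        mask = (grp["_screen"] < lo) | (grp["_screen"] > hi)
        flagged_idx.extend(grp.index[mask])

    hits = sub.loc[flagged_idx, list(OUTLIER_COLUMNS)].copy()
    hits = hits.sort_values(["Activity Start Date", "Monitoring Location ID"]).reset_index(
        drop=True
    )

    if plot_path is not None:
        _plot_outliers(sub, hits, param, group, scale, Path(plot_path))
    return hits if outliers_table else hits.iloc[0:0]


def _plot_outliers(
    sub: pd.DataFrame,
    hits: pd.DataFrame,
    param: str,
    group: str,
    scale: str,
    path: Path,
) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = list(dict.fromkeys(sub["_group"]))
    data = [sub.loc[sub["_group"] == g, "_value"].to_numpy() for g in labels]
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.boxplot(data, tick_labels=labels, whis=1.5)
    if scale == "log":
        ax.set_yscale("log")
    hit_keys = set(zip(hits["Monitoring Location ID"], hits["Activity Start Date"]))
    for i, g in enumerate(labels, start=1):
        grp = sub[sub["_group"] == g]
        for _, row in grp.iterrows():
            key = (row["Monitoring Location ID"], row["Activity Start Date"])
            if key in hit_keys:
                ax.annotate(
                    row["Monitoring Location ID"],
                    (i, row["_value"]),
                    textcoords="offset points",
                    xytext=(5, 0),
                    fontsize=7,
                )
    unit = sub["Result Unit"].iloc[0] if len(sub) else ""
    ax.set_ylabel(f"{param} ({unit})" if unit else param)
    ax.set_xlabel(group)
    ax.set_title(f"Potential outliers: {param} by {group}")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def batch_outliers(
    bundle: InputBundle,
    group: str = "month",
    format: str = "images",
    output_dir: str | Path = ".",
) -> list[Path]:
    """Screen every parameter in the results file; write plots or one document.

    ``format="images"`` writes one PNG per parameter (file names derived from
    the parameter name); ``format="doc"`` writes a single HTML document that
    embeds all plots, in deterministic parameter order.
    """
    res = bundle.results
    if res.empty:
        raise ValueError("results table is empty; nothing to screen")
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    params = sorted(res["Characteristic Name"].unique())
    written: list[Path] = []
    png_paths: list[tuple[str, Path]] = []
    for p in params:
        fname = p.replace("/", "-").replace(" ", "_").replace(".", "")
        png = output_dir / f"outliers_{fname}.png"
        detect_outliers(bundle, p, group=group, plot_path=png)
        png_paths.append((p, png))
    if format == "images":
        return [png for _, png in png_paths]
    if format != "doc":
        raise ValueError(f"unknown format {format!r}: use 'doc' or 'images'")
    import base64

    parts = ["<!DOCTYPE html><html><head><meta charset='utf-8'></head><body>"]
    parts.append("<h1>Outlier screening</h1>")
    for p, png in png_paths:
        b64 = base64.b64encode(png.read_bytes()).decode()
        parts.append(f"<h2>{p}</h2><img src='data:image/png;base64,{b64}'/>")
        png.unlink()
    parts.append("</body></html>")
    doc = output_dir / "outliers.html"
    doc.write_text("\n".join(parts))
    written.append(doc)
    return written
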