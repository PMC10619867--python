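"""Seasonal, date-series, per-site, and spatial summaries of monitoring results.

Summary behavior is driven by the accuracy DQOs: a parameter whose DQO row
carries a ``log`` token is treated as log-distributed, so ``auto`` settings
resolve to a log10 axis and the geometric mean; otherwise the arithmetic mean
on a linear axis.  Censored values are substituted (BDL -> MDL/2, AQL -> UQL)
exactly as in outlier screening so all views agree on the numbers.

Confidence intervals on date aggregates are normal-theory ``mean +/- 1.96*SE``
computed on the resolved scale — for geometric means the interval is computed
on log10 values and back-transformed, giving an asymmetric interval on the
raw scale.

Threshold overlays are pure presentation: reference lines with their source
shown in the legend, never part of the computed statistics.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Any, Callable, Sequence

import numpy as np
import pandas as pd

from .outlier_screen import substitute_censored
from .tabular_io import InputBundle, select_rule

logger = logging.getLogger(__name__)

__all__ = [
    "auto_settings",
    "summarize_groups",
    "date_series",
    "spatial_aggregate",
    "SUMMARY_FUNCTIONS",
]


def _geomean(x: np.ndarray) -> float:
    if np.any(x <= 0):
        raise ValueError("geometric mean requires positive values")
    return float(np.exp(np.mean(np.log(x))))


SUMMARY_FUNCTIONS: dict[str, Callable[[np.ndarray], float]] = {
    "mean": lambda x: float(np.mean(x)),
    "geomean": _geomean,
    "median": lambda x: float(np.median(x)),
    "min": lambda x: float(np.min(x)),
    "max": lambda x: float(np.max(x)),
}


def auto_settings(
    param: str,
    bundle: InputBundle,
    sumfun: str = "auto",
    yscl: str = "auto",
) -> tuple[str, str]:
    """Resolve ``auto`` summary-function and axis-scale settings for a parameter.

    ``auto`` resolves to ``("log", "geomean")`` iff the parameter's accuracy
    DQO row carries a ``log`` token, else ``("linear", "mean")``.  Explicit
    settings pass through unchanged.
    """
    rules = bundle.rules.get(param, [])
    hint = "log" if any(r.scale_hint == "log" for r in rules) else "linear"
    scale = hint if yscl == "auto" else yscl
    if sumfun == "auto":
        fun = "geomean" if hint == "log" else "mean"
    else:
        if sumfun not in SUMMARY_FUNCTIONS:
            raise ValueError(
                f"unknown summary function {sumfun!r}: "
                f"use auto, {', '.join(SUMMARY_FUNCTIONS)}"
            )
        fun = sumfun
    if scale not in ("linear", "log"):
        raise ValueError(f"unknown y-scale {yscl!r}: use auto, linear, or log")
    return scale, fun


def _param_table(bundle: InputBundle, param: str) -> pd.DataFrame:
    """Regular observations of one parameter with numeric values attached."""
    res = bundle.results
    regular = set(bundle.config["regular_activity_types"])
    sub = res[
        (res["Characteristic Name"] == param) & res["Activity Type"].isin(regular)
    ].copy()
    if sub.empty:
        raise ValueError(f"parameter {param!r} has no regular records in results")
    rules = bundle.rules.get(param, [])
    rule = select_rule(rules, None) if rules else None
    values, kept = substitute_censored(list(sub["Result Value"]), rule)
    sub = sub.iloc[kept].copy()
    sub["_value"] = values
    return sub


def _apply_fun(fun: str, x: np.ndarray, param: str) -> float:
    try:
        return SUMMARY_FUNCTIONS[fun](x)
    except ValueError as exc:
        raise ValueError(f"{exc} (parameter {param})") from exc


def _thresholds_for(
    bundle: InputBundle, param: str, thresh: str
) -> list[dict[str, Any]]:
    if thresh in ("none", None):
        return []
    table = bundle.config.get("thresholds", {})
    return list(table.get(param, {}).get(thresh, []))


def _season_labels(sub: pd.DataFrame, group: str) -> pd.Series:
    dates = pd.to_datetime(sub["Activity Start Date"])
    if group == "month":
        return dates.dt.strftime("%b")
    if group == "week":
        return dates.dt.isocalendar().week.astype(int).astype(str)
    raise ValueError(f"unknown season group {group!r}: use month or week")


def summarize_groups(
    bundle: InputBundle,
    param: str,
    view: str = "season",
    group: str = "month",
    sites: Sequence[str] | None = None,
    resultatt: Sequence[str] | None = None,
    type: str = "box",
    thresh: str = "none",
    sumfun: str = "auto",
    plot_path: str | Path | None = None,
) -> pd.DataFrame:
    """Summary statistics per seasonal group or per site, optionally plotted.

    ``view="season"`` groups observations by calendar month or ISO week;
    ``view="site"`` groups by station, keeping the input order of an explicit
    *sites* filter on the axis.  An optional *resultatt* filter splits groups
    by the free-form Result Attribute labels (e.g. DRY/WET).  Output has one
    row per group (x attribute value) with quartile box statistics and the
    resolved summary statistic.
    """
    scale, fun = auto_settings(param, bundle, sumfun=sumfun)
    sub = _param_table(bundle, param)

    if view == "season":
        sub["_group"] = _season_labels(sub, group)
        order = list(dict.fromkeys(sub["_group"]))
    elif view == "site":
        if sites is not None:
            missing = [s for s in sites if s not in set(sub["Monitoring Location ID"])]
            if missing:
                raise ValueError(
                    f"site(s) not present for {param}: {', '.join(missing)}"
                )
            sub = sub[sub["Monitoring Location ID"].isin(sites)].copy()
            order = list(sites)
        else:
            order = sorted(sub["Monitoring Location ID"].unique())
        sub["_group"] = sub["Monitoring Location ID"]
    else:
        raise ValueError(f"unknown view {view!r}: use season or site")

    if resultatt is not None:
        available = sorted(v for v in sub["Result Attribute"].unique() if v)
        bad = [v for v in resultatt if v not in available]
        if bad:
            raise ValueError(
                f"Result Attribute value(s) {', '.join(bad)} absent; "
                f"available: {', '.join(available) or '(none)'}"
            )
        sub = sub[sub["Result Attribute"].isin(resultatt)].copy()

    att_values: list[str | None] = (
        list(resultatt) if resultatt is not None else [None]
    )
    rows = []
    for g in order:
        for att in att_values:
            grp = sub[sub["_group"] == g]
            if att is not None:
                grp = grp[grp["Result Attribute"] == att]
            if grp.empty:
                continue
            x = grp["_value"].to_numpy(dtype=float)
            q1, q2, q3 = np.quantile(x, [0.25, 0.5, 0.75])
            rows.append(
                {
                    "group_label": g if att is None else f"{g} ({att})",
                    "stat": _apply_fun(fun, x, param),
                    "q1": float(q1),
                    "median": float(q2),
                    "q3": float(q3),
                    "min": float(np.min(x)),
                    "max": float(np.max(x)),
                    "n": int(len(x)),
                }
            )
    out = pd.DataFrame(
        rows, columns=["group_label", "stat", "q1", "median", "q3", "min", "max", "n"]
    )
    if plot_path is not None:
        _plot_groups(sub, out, param, scale, type, _thresholds_for(bundle, param, thresh), Path(plot_path))
    return out


def _plot_groups(
    sub: pd.DataFrame,
    summary: pd.DataFrame,
    param: str,
    scale: str,
    type: str,
    thresholds: list[dict[str, Any]],
    path: Path,
) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = list(summary["group_label"])
    fig, ax = plt.subplots(figsize=(7, 4))
    if type.startswith("bar"):
        ax.bar(range(len(labels)), summary["stat"], color="#0072b2")
        ax.set_xticks(range(len(labels)), labels)
    else:
        groups = [
            sub.loc[sub["_group"] == g.split(" (")[0], "_value"].to_numpy()
            for g in labels
        ]
        ax.boxplot(groups, tick_labels=labels, whis=1.5)
        if "jitter" in type:
            rng = np.random.default_rng(0)  # presentation jitter only
            for i, vals in enumerate(groups, start=1):
                ax.plot(
                    i + rng.uniform(-0.15, 0.15, len(vals)),
                    vals,
                    "o",
                    ms=3,
                    alpha=0.5,
                    color="#0072b2",
                )
    if scale == "log":
        ax.set_yscale("log")
    for t in thresholds:
        ax.axhline(t["value"], ls="--", color="#d55e00", label=f"{t['label']} ({t['source']})")
    if thresholds:
        ax.legend(fontsize=7, loc="upper left", bbox_to_anchor=(0, 1.25))
    unit = sub["Result Unit"].iloc[0] if len(sub) else ""
    ax.set_ylabel(f"{param} ({unit})" if unit else param)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def date_series(
    bundle: InputBundle,
    param: str,
    group: str = "all",
    thresh: str = "none",
    confint: bool = False,
    sumfun: str = "auto",
    plot_path: str | Path | None = None,
) -> pd.DataFrame:
    """Aggregate results per sample date, by site, location group, or overall.

    With ``confint=True`` a 95% normal-theory interval ``stat +/- 1.96*SE`` is
    attached for groups with at least two observations, computed on the log10
    scale and back-transformed when the resolved summary is the geometric
    mean.  ``group="locgroup"`` requires the site metadata file; sites without
    a Location Group entry are dropped with a notice.
    """
    scale, fun = auto_settings(param, bundle, sumfun=sumfun)
    sub = _param_table(bundle, param)

    if group == "site":
        sub["_group"] = sub["Monitoring Location ID"]
    elif group == "locgroup":
        if bundle.sites is None:
            raise ValueError("group='locgroup' requires the site metadata file")
        lookup = dict(
            zip(bundle.sites["Monitoring Location ID"], bundle.sites["Location Group"])
        )
        sub["_group"] = sub["Monitoring Location ID"].map(lookup).fillna("")
        dropped = sorted(sub.loc[sub["_group"] == "", "Monitoring Location ID"].unique())
        if dropped:
            logger.warning(
                "site(s) without a Location Group dropped: %s", ", ".join(dropped)
            )
            sub = sub[sub["_group"] != ""].copy()
    elif group == "all":
        sub["_group"] = "all"
    else:
        raise ValueError(f"unknown group {group!r}: use site, locgroup, or all")

    rows = []
    for (date, g), grp in sub.groupby(["Activity Start Date", "_group"], sort=True):
        x = grp["_value"].to_numpy(dtype=float)
        stat = _apply_fun(fun, x, param)
        lo = hi = None
        if confint and len(x) >= 2:
            if fun == "geomean":
                lx = np.log10(x)
                se = float(np.std(lx, ddof=1) / math.sqrt(len(lx)))
                m = float(np.mean(lx))
                lo, hi = 10 ** (m - 1.96 * se), 10 ** (m + 1.96 * se)
            else:
                se = float(np.std(x, ddof=1) / math.sqrt(len(x)))
                lo, hi = stat - 1.96 * se, stat + 1.96 * se
        rows.append(
            {"date": date, "group_label": g, "stat": stat, "lo": lo, "hi": hi, "n": len(x)}
        )
    out = pd.DataFrame(rows, columns=["date", "group_label", "stat", "lo", "hi", "n"])
    if plot_path is not None:
        _plot_dates(out, sub, param, scale, _thresholds_for(bundle, param, thresh), Path(plot_path))
    return out


def _plot_dates(
    series: pd.DataFrame,
    sub: pd.DataFrame,
    param: str,
    scale: str,
    thresholds: list[dict[str, Any]],
    path: Path,
) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for g, grp in series.groupby("group_label"):
        dates = pd.to_datetime(grp["date"])
        ax.plot(dates, grp["stat"], "-o", ms=4, label=g)
        if grp["lo"].notna().any():
            ax.fill_between(
                dates,
                grp["lo"].astype(float),
                grp["hi"].astype(float),
                alpha=0.2,
            )
    if scale == "log":
        ax.set_yscale("log")
    for t in thresholds:
        ax.axhline(t["value"], ls="--", color="#d55e00", label=f"{t['label']} ({t['source']})")
    ax.legend(fontsize=7)
    unit = sub["Result Unit"].iloc[0] if len(sub) else ""
    ax.set_ylabel(f"{param} ({unit})" if unit else param)
    fig.autofmt_xdate()
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def spatial_aggregate(
    bundle: InputBundle,
    param: str,
    sumfun: str = "auto",
    plot_path: str | Path | None = None,
    extra_layers: Sequence[tuple[Sequence[float], Sequence[float]]] | None = None,
) -> pd.DataFrame:
    """Aggregate one parameter per site, joined to coordinates for mapping.

    Returns one row per site with at least one observation: site id,
    latitude, longitude, the aggregate statistic, and n.  Sites present in
    the results but missing from the site metadata are dropped with a notice.
    The optional rendering writes a simple lon/lat scatter colored by the
    statistic; *extra_layers* accepts user-supplied ``(x, y)`` line layers
    (e.g. digitized hydrography) drawn underneath.
    """
    if bundle.sites is None:
        raise ValueError("spatial aggregation requires the site metadata file")
    _, fun = auto_settings(param, bundle, sumfun=sumfun)
    sub = _param_table(bundle, param)
    sites = bundle.sites.set_index("Monitoring Location ID")
    known = set(sites.index)
    missing = sorted(set(sub["Monitoring Location ID"]) - known)
    if missing:
        logger.warning(
            "site(s) in results but absent from site metadata dropped: %s",
            ", ".join(missing),
        )
        sub = sub[sub["Monitoring Location ID"].isin(known)].copy()

    rows = []
    for site, grp in sub.groupby("Monitoring Location ID", sort=True):
        x = grp["_value"].to_numpy(dtype=float)
        rows.append(
            {
                "Monitoring Location ID": site,
                "Latitude": float(sites.loc[site, "Monitoring Location Latitude"]),
                "Longitude": float(sites.loc[site, "Monitoring Location Longitude"]),
                "stat": _apply_fun(fun, x, param),
                "n": int(len(x)),
            }
        )
    out = pd.DataFrame(
        rows, columns=["Monitoring Location ID", "Latitude", "Longitude", "stat", "n"]
    )
    if plot_path is not None:
        _plot_map(out, param, Path(plot_path), extra_layers or [])
    return out


def _plot_map(
    agg: pd.DataFrame,
    param: str,
    path: Path,
    layers: Sequence[tuple[Sequence[float], Sequence[float]]],
) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    for xs, ys in layers:
        ax.plot(xs, ys, color="#9ecae1", lw=1, zorder=1)
    sc = ax.scatter(
        agg["Longitude"], agg["Latitude"], c=agg["stat"], cmap="viridis", s=60, zorder=2
    )
    for _, row in agg.iterrows():
        ax.annotate(
            row["Monitoring Location ID"],
            (row["Longitude"], row["Latitude"]),
            textcoords="offset points",
            xytext=(5, 3),
            fontsize=7,
        )
    fig.colorbar(sc, ax=ax, label=param)
    ax.set_xlabel("Longitude")
    ax.set_ylabel("Latitude")
    ax.set_aspect("equal", adjustable="datalim")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
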