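"""Tiny deterministic Markdown/HTML renderers for report documents.

A document is a list of ``(kind, payload)`` blocks with kinds ``title``,
``heading``, ``para``, and ``table`` (payload: :class:`pandas.DataFrame`).
Output contains no timestamps, so identical inputs render byte-identically.
"""

from __future__ import annotations

import html as _html
from typing import Any, Iterable

import pandas as pd

__all__ = ["markdown_table", "doc_to_markdown", "doc_to_html"]


def _cell(v: Any) -> str:
    if v is None:
        return ""
    if isinstance(v, float) and v == int(v):
        return str(int(v))
    s = str(v)
    return "" if s == "nan" else s


def markdown_table(df: pd.DataFrame) -> str:
    headers = [_cell(c) for c in df.columns]
    rows = [[_cell(v) for v in row] for row in df.itertuples(index=False)]
    widths = [
        max(len(h), *(len(r[i]) for r in rows)) if rows else len(h)
        for i, h in enumerate(headers)
    ]
    def line(cells: Iterable[str]) -> str:
        return "| " + " | ".join(c.ljust(w) for c, w in zip(cells, widths)) + " |"
    out = [line(headers), line("-" * w for w in widths)]
    out.extend(line(r) for r in rows)
    return "\n".join(out)


def doc_to_markdown(doc: list[tuple[str, Any]]) -> str:
    parts: list[str] = []
    for kind, payload in doc:
        if kind == "title":
            parts.append(f"# {payload}")
        elif kind == "heading":
            parts.append(f"## {payload}")
        elif kind == "para":
            parts.append(str(payload))
        elif kind == "table":
            parts.append(markdown_table(payload))
        else:
            raise ValueError(f"unknown block kind {kind!r}")
    return "\n\n".join(parts) + "\n"


def _html_table(df: pd.DataFrame) -> str:
    head = "".join(f"<th>{_html.escape(_cell(c))}</th>" for c in df.columns)
    body = "".join(
        "<tr>"
        + "".join(
            # keep the textual MISS marker and add a class for two-color styling
            (
                f'<td class="miss">{_html.escape(_cell(v))}</td>'
                if _cell(v) == "MISS"
                else f"<td>{_html.escape(_cell(v))}</td>"
            )
            for v in row
        )
        + "</tr>"
        for row in df.itertuples(index=False)
    )
    return f"<table><thead><tr>{head}</tr></thead><tbody>{body}</tbody></table>"


_CSS = (
    "table{border-collapse:collapse}td,th{border:1px solid #999;padding:4px 8px}"
    # color-blind-friendly pair (blue hit background handled per-table if needed)
    "td.miss{background:#d55e00;color:#fff;font-weight:bold}"
)


def doc_to_html(doc: list[tuple[str, Any]]) -> str:
    parts: list[str] = [
        "<!DOCTYPE html>",
        "<html><head><meta charset='utf-8'>",
        f"<style>{_CSS}</style>",
        "</head><body>",
    ]
    for kind, payload in doc:
        if kind == "title":
            parts.append(f"<h1>{_html.escape(str(payload))}</h1>")
        elif kind == "heading":
            parts.append(f"<h2>{_html.escape(str(payload))}</h2>")
        elif kind == "para":
            parts.append(f"<p>{_html.escape(str(payload))}</p>")
        elif kind == "table":
            parts.append(_html_table(payload))
        else:
            raise ValueError(f"unknown block kind {kind!r}")
    parts.append("</body></html>")
    return "\n".join(parts)
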