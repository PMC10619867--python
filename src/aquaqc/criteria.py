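"""Criterion grammar for data-quality-objective (DQO) cells.

An accuracy DQO cell holds one of:

* a comparison ``<op> <number>[%]`` with ``op`` in ``< <= > >=`` — the trailing
  ``%`` marks a *relative* criterion (applied to a percent statistic such as
  the relative percent difference of a duplicate pair) while its absence marks
  an *absolute* criterion on the measured value or difference;
* a bare censoring token ``BDL`` or ``AQL`` — the QC sample must itself be
  censored;
* the token ``log`` — no criterion, only a hint that the parameter is
  summarized and plotted on a log10 scale;
* an empty cell — no check of this type applies to the parameter.

``parse_criterion`` is total over these forms and raises ``CriterionError``
with the offending text otherwise.  ``str()`` of a parsed criterion
round-trips to a canonical form of the input.
"""

from __future__ import annotations

import operator
import re
from dataclasses import dataclass
from typing import Callable

__all__ = [
    "Criterion",
    "CriterionError",
    "parse_criterion",
    "parse_value_range",
    "is_censored",
]

_OPS: dict[str, Callable[[float, float], bool]] = {
    "<": operator.lt,
    "<=": operator.le,
    ">": operator.gt,
    ">=": operator.ge,
}

_CRIT_RE = re.compile(r"^\s*(<=|>=|<|>)\s*([0-9]*\.?[0-9]+)\s*(%?)\s*$")


class CriterionError(ValueError):
    """Raised for a DQO cell that does not parse under the criterion grammar."""


def is_censored(token: object) -> bool:
    """True if *token* is a censoring marker (``BDL``/``AQL`` string)."""
    return isinstance(token, str) and token.strip().upper() in ("BDL", "AQL")


@dataclass(frozen=True)
class Criterion:
    """One parsed accuracy criterion.

    ``kind`` is ``"percent"`` for relative criteria, ``"absolute"`` for plain
    numeric ones, and ``"censored"`` for a bare BDL/AQL requirement (``op``
    and ``magnitude`` are unused in that case).
    """

    op: str
    magnitude: float
    kind: str  # "percent" | "absolute" | "censored"
    token: str = ""  # original censor token for kind == "censored"

    def check(self, statistic: float) -> bool:
        """Apply the comparison to a computed statistic (value, diff, or RPD)."""
        if self.kind == "censored":
            raise CriterionError("censored criterion has no numeric comparison")
        return _OPS[self.op](statistic, self.magnitude)

    def __str__(self) -> str:
        if self.kind == "censored":
            return self.token
        mag = f"{self.magnitude:g}"
        return f"{self.op} {mag}%" if self.kind == "percent" else f"{self.op} {mag}"


def parse_criterion(cell: object) -> Criterion | None:
    """Parse one DQO cell; return ``None`` for empty or log-hint-only cells."""
    if cell is None:
        return None
    text = str(cell).strip()
    if text == "" or text.lower() in ("nan", "na", "-"):
        return None
    if text.lower() == "log":
        return None
    if is_censored(text):
        return Criterion(op="", magnitude=float("nan"), kind="censored", token=text.upper())
    m = _CRIT_RE.match(text)
    if m is None:
        raise CriterionError(f"cannot parse criterion {text!r}")
    op, number, pct = m.groups()
    kind = "percent" if pct else "absolute"
    magnitude = float(number)
    if kind == "percent" and magnitude < 0:
        raise CriterionError(f"negative percent criterion {text!r}")
    return Criterion(op=op, magnitude=magnitude, kind=kind)


_RANGE_RE = re.compile(r"^\s*(<=|>=|<|>)\s*([0-9]*\.?[0-9]+)\s*$")


def parse_value_range(cell: object) -> tuple[float, float] | None:
    """Parse a Value Range cell into a closed-open interval ``(lo, hi)``.

    Accepted forms: empty/``all`` (no restriction, returns ``None``),
    ``<= x`` / ``< x`` (interval ``(-inf, x]`` / ``(-inf, x)`` — both mapped to
    an upper bound), ``> x`` / ``>= x`` (lower bound), and ``a - b``.
    The returned tuple is ``(lo, hi)`` with infinities for open ends; callers
    test membership with ``lo <= v <= hi`` after a strictness-free convention
    (a value on a shared boundary matches the narrower of two rules).
    """
    if cell is None:
        return None
    text = str(cell).strip()
    if text == "" or text.lower() in ("nan", "na", "all", "-"):
        return None
    m = _RANGE_RE.match(text)
    if m:
        op, number = m.groups()
        x = float(number)
        return (float("-inf"), x) if op in ("<", "<=") else (x, float("inf"))
    parts = re.split(r"\s*-\s*", text)
    if len(parts) == 2:
        try:
            lo, hi = float(parts[0]), float(parts[1])
        except ValueError as exc:
            raise CriterionError(f"cannot parse value range {text!r}") from exc
        if lo > hi:
            raise CriterionError(f"inverted value range {text!r}")
        return (lo, hi)
    raise CriterionError(f"cannot parse value range {text!r}")
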