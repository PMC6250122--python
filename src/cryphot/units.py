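"""Time-unit handling.

All numerical work in this package is carried out in seconds; the regimes
covered span femtoseconds (electron transfer) to minutes (flavin
re-oxidation), and a single base unit avoids conversion bugs.  User-facing
interfaces accept unit-suffixed strings such as ``"100fs"``, ``"46ps"``,
``"1us"`` or ``"187ms"``.
"""

from __future__ import annotations

import re

#: multiplicative factors to seconds
TIME_UNITS: dict[str, float] = {
    "fs": 1e-15,
    "ps": 1e-12,
    "ns": 1e-9,
    "us": 1e-6,
    "μs": 1e-6,  # μs
    "µs": 1e-6,  # µs (micro sign)
    "ms": 1e-3,
    "s": 1.0,
    "min": 60.0,
}

_TIME_RE = re.compile(r"^\s*([+-]?\d+\.?\d*(?:[eE][+-]?\d+)?)\s*([a-zA-Zμµ]*)\s*$")


def parse_time(value: str | float, default_unit: str = "s") -> float:
    """Parse a time quantity into seconds.

    Accepts a bare number (interpreted in ``default_unit``) or a string with
    a unit suffix, e.g. ``"848fs"``, ``"46 ps"``, ``"inf"``.
    """
    if isinstance(value, (int, float)):
        return float(value) * TIME_UNITS[default_unit]
    s = value.strip()
    if s.lower() in ("inf", "+inf", "infinity"):
        return float("inf")
    m = _TIME_RE.match(s)
    if m is None:
        raise ValueError(f"cannot parse time quantity {value!r}")
    num, unit = m.groups()
    unit = unit or default_unit
    if unit not in TIME_UNITS:
        raise ValueError(f"unknown time unit {unit!r} in {value!r}")
    return float(num) * TIME_UNITS[unit]


def format_time(seconds: float) -> str:
    """Render a time in seconds with a sensible SI suffix (for reports)."""
    if seconds == 0:
        return "0 s"
    if not (seconds == seconds) or seconds in (float("inf"), float("-inf")):
        return str(seconds)
    a = abs(seconds)
    for unit, factor in (("fs", 1e-15), ("ps", 1e-12), ("ns", 1e-9),
                         ("us", 1e-6), ("ms", 1e-3), ("s", 1.0)):
        if a < factor * 1e3 or unit == "s":
            return f"{seconds / factor:.4g} {unit}"
    return f"{seconds:.4g} s"
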