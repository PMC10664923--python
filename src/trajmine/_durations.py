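"""Parsing of human-readable duration tokens into whole days.

Gap arithmetic throughout the package is done in whole days; calendar
months and years are mapped to fixed day counts so that a configured
window is unambiguous regardless of the dates it is applied to.
"""

from __future__ import annotations

import re

# Fixed conversions: 6 months = 183 days, 5 years = 1826 days.
_DAYS_PER_UNIT = {"D": 1, "W": 7, "M": 30.5, "Y": 365.25}

_TOKEN_RE = re.compile(r"^\s*(\d+(?:\.\d+)?)\s*([DWMY])\s*$", re.IGNORECASE)


def parse_duration(token: str | int | float) -> int:
    """Parse a duration token such as ``"5Y"``, ``"6M"``, ``"1D"`` into days.

    Bare numbers (int, float or numeric string) are taken as days.
    Months count 30.5 days and years 365.25 days, rounded to the nearest
    whole day after multiplication (so ``"6M"`` is 183 days and ``"5Y"``
    is 1826 days).
    """
    if isinstance(token, (int, float)):
        return int(round(token))
    token = token.strip()
    if re.fullmatch(r"\d+", token):
        return int(token)
    m = _TOKEN_RE.match(token)
    if m is None:
        raise ValueError(f"cannot parse duration token {token!r}")
    value = float(m.group(1))
    unit = m.group(2).upper()
    return int(round(value * _DAYS_PER_UNIT[unit]))
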