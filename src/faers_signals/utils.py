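"""Small shared helpers: term normalization, FAERS date parsing, age units."""

from __future__ import annotations

import re
from datetime import date

import numpy as np
import pandas as pd

_WS = re.compile(r"\s+")

#: Divisors converting an age value in the given unit code to years.
AGE_UNIT_PER_YEAR = {
    "YR": 1.0,
    "MON": 12.0,
    "WK": 52.0,
    "DY": 365.25,
    "HR": 8766.0,
}

#: Ages above this (in years) are treated as data-entry noise and set missing.
MAX_PLAUSIBLE_AGE_YEARS = 120.0


def normalize_term(value) -> str | None:
    """Canonicalize a free-text term for comparison.

    Trims, collapses internal whitespace, and casefolds, so that
    ``"  Pancreatitis "`` and ``"PANCREATITIS"`` compare equal. Returns
    ``None`` for missing/empty input.
    """
    if value is None or (isinstance(value, float) and np.isnan(value)) or value is pd.NA:
        return None
    text = _WS.sub(" ", str(value)).strip()
    if not text:
        return None
    return text.casefold()


def parse_faers_dates(raw: pd.Series) -> tuple[pd.Series, int]:
    """Parse a column of FAERS ``YYYYMMDD`` date strings.

    Returns the parsed datetime series and the number of non-blank values
    that failed to parse (impossible calendar dates such as ``20190230``
    count as failures and become missing).
    """
    text = raw.astype("string").str.strip()
    blank = text.isna() | (text == "")
    parsed = pd.to_datetime(text.where(~blank), format="%Y%m%d", errors="coerce")
    n_bad = int((parsed.isna() & ~blank).sum())
    return parsed, n_bad


def format_faers_date(value) -> str:
    if pd.isna(value):
        return ""
    if isinstance(value, (pd.Timestamp, date)):
        return pd.Timestamp(value).strftime("%Y%m%d")
    return str(value)


def age_to_years(age_value, age_unit) -> float:
    """Convert an (age, unit-code) pair to years; NaN when unconvertible.

    Implausible results (> 120 y) are also mapped to NaN rather than kept,
    since free-text FAERS ages routinely contain unit mistakes.
    """
    if pd.isna(age_value) or pd.isna(age_unit):
        return float("nan")
    divisor = AGE_UNIT_PER_YEAR.get(str(age_unit).strip().upper())
    if divisor is None:
        return float("nan")
    years = float(age_value) / divisor
    if years < 0 or years > MAX_PLAUSIBLE_AGE_YEARS:
        return float("nan")
    return years


#: Age-group edges used in descriptive summaries (right-closed bins).
AGE_BIN_EDGES = [0, 18, 30, 40, 50, 60, 70, float("inf")]
AGE_BIN_LABELS = ["0-18", "19-30", "31-40", "41-50", "51-60", "61-70", ">70"]


def bin_age_years(age_years: pd.Series) -> pd.Series:
    """Assign decade-style age groups; missing ages stay missing."""
    return pd.cut(
        age_years,
        bins=AGE_BIN_EDGES,
        labels=AGE_BIN_LABELS,
        include_lowest=True,
        right=True,
    )
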