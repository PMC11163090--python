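"""2x2 contingency tables and the frequentist disproportionality indices.

For one exposure (a drug class or a single drug) against one adverse-event
term, the cells are

=====  ==========================================
``a``  event reports for the studied exposure
``b``  non-event reports for the studied exposure
``c``  event reports for all other exposures
``d``  non-event reports for all other exposures
=====  ==========================================

The comparator is the whole cleaned cohort: every report whose
primary-suspect set does not include the studied exposure, not merely the
other studied classes.

ROR = (a.d)/(b.c) with 95% CI exp(ln ROR +/- 1.96*sqrt(1/a+1/b+1/c+1/d));
PRR = [a/(a+b)] / [c/(c+d)] with
95% CI exp(ln PRR +/- 1.96*sqrt(1/a - 1/(a+b) + 1/c - 1/(c+d))).
When any cell is zero the Haldane-Anscombe correction (add 0.5 to all four
cells) is applied to both the point estimate and the interval, and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .utils import normalize_term

__all__ = [
    "ContingencyTable",
    "RatioEstimate",
    "FrequentistMetrics",
    "DegenerateTableError",
    "build_contingency",
    "ror",
    "prr",
    "frequentist_metrics",
    "pairwise_ror",
]

Z95 = 1.959963984540054  # two-sided 95% normal quantile


class DegenerateTableError(ValueError):
    """All cells zero: no information to estimate a ratio from."""


@dataclass(frozen=True)
class ContingencyTable:
    a: int
    b: int
    c: int
    d: int
    exposure_label: str = ""
    event_label: str = ""

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def n(self) -> int:
        """Number of event reports for the exposure (the signal count)."""
        return self.a

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class RatioEstimate:
    value: float
    lo: float
    hi: float
    correction_applied: bool = False


@dataclass(frozen=True)
class FrequentistMetrics:
    ror: float
    ror_lo: float
    ror_hi: float
    prr: float
    prr_lo: float
    prr_hi: float
    n: int
    correction_applied: bool


def _cells(table: ContingencyTable) -> tuple[float, float, float, float, bool]:
    a, b, c, d = float(table.a), float(table.b), float(table.c), float(table.d)
    if a + b + c + d == 0:
        raise DegenerateTableError("all four contingency cells are zero")
    corrected = min(a, b, c, d) == 0
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return a, b, c, d, corrected


def ror_arrays(a, b, c, d):
    """Vectorized ROR with CI; zero-cell tables get the 0.5 correction."""
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    corrected = np.minimum(np.minimum(a, b), np.minimum(c, d)) == 0
    a, b, c, d = (x + 0.5 * corrected for x in (a, b, c, d))
    est = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return est, est * np.exp(-Z95 * se), est * np.exp(Z95 * se), corrected


def prr_arrays(a, b, c, d):
    """Vectorized PRR with CI; zero-cell tables get the 0.5 correction."""
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    corrected = np.minimum(np.minimum(a, b), np.minimum(c, d)) == 0
    a, b, c, d = (x + 0.5 * corrected for x in (a, b, c, d))
    est = (a / (a + b)) / (c / (c + d))
    se = np.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
    return est, est * np.exp(-Z95 * se), est * np.exp(Z95 * se), corrected


def ror(table: ContingencyTable) -> RatioEstimate:
    """Reporting odds ratio with 95% confidence interval."""
    a, b, c, d, corrected = _cells(table)
    est, lo, hi, _ = ror_arrays(table.a, table.b, table.c, table.d)
    return RatioEstimate(float(est), float(lo), float(hi), corrected)


def prr(table: ContingencyTable) -> RatioEstimate:
    """Proportional reporting ratio with 95% confidence interval."""
    a, b, c, d, corrected = _cells(table)
    est, lo, hi, _ = prr_arrays(table.a, table.b, table.c, table.d)
    return RatioEstimate(float(est), float(lo), float(hi), corrected)


def frequentist_metrics(table: ContingencyTable) -> FrequentistMetrics:
    r = ror(table)
    p = prr(table)
    return FrequentistMetrics(
        ror=r.value, ror_lo=r.lo, ror_hi=r.hi,
        prr=p.value, prr_lo=p.lo, prr_hi=p.hi,
        n=table.a, correction_applied=r.correction_applied,
    )


def _exposure_mask(cohort: pd.DataFrame, exposure: str, class_map=None) -> pd.Series:
    """Boolean mask of cohort reports carrying the exposure as PS.

    ``exposure`` may be a class name (matched against ``drug_classes``) or a
    literal drug name (matched, normalized, against ``ps_drugs``).
    """
    classes = set()
    for cs in cohort["drug_classes"]:
        classes.update(cs)
    if class_map is not None:
        classes.update(class_map.classes)
    if exposure in classes:
        return cohort["drug_classes"].apply(lambda cs: exposure in cs)
    name = normalize_term(exposure)
    mask = cohort["ps_drugs"].apply(lambda ds: name in ds)
    if not mask.any():
        known = set()
        for ds in cohort["ps_drugs"]:
            known.update(ds)
        if name not in known:
            raise LookupError(
                f"exposure {exposure!r} is neither a known class nor a drug "
                "present in the cohort"
            )
    return mask


def build_contingency(
    cohort: pd.DataFrame,
    exposure: str,
    event_label: str = "",
    class_map=None,
) -> ContingencyTable:
    """Count the 2x2 cells for one exposure against the cohort's event flag.

    The margins satisfy a+b = reports with the exposure, a+c = all event
    reports, and a+b+c+d = cohort size.
    """
    exposed = _exposure_mask(cohort, exposure, class_map)
    event = cohort["event_flag"].astype(bool)
    return ContingencyTable(
        a=int((exposed & event).sum()),
        b=int((exposed & ~event).sum()),
        c=int((~exposed & event).sum()),
        d=int((~exposed & ~event).sum()),
        exposure_label=exposure,
        event_label=event_label,
    )


def pairwise_ror(
    cohort: pd.DataFrame,
    drug: str,
    reference: str,
    event_label: str = "",
) -> tuple[RatioEstimate, ContingencyTable]:
    """ROR of ``drug`` against a same-class ``reference`` drug.

    The 2x2 is restricted to reports exposed (PS) to either drug: a/b come
    from the studied drug's reports, c/d from the reference's. A report
    listing both drugs as PS contributes to both arms.
    """
    if normalize_term(drug) == normalize_term(reference):
        raise ValueError("drug and reference must differ")
    drug_mask = _exposure_mask(cohort, drug)
    try:
        ref_mask = _exposure_mask(cohort, reference)
    except LookupError:
        raise LookupError(f"reference drug {reference!r} absent from cohort")
    event = cohort["event_flag"].astype(bool)
    table = ContingencyTable(
        a=int((drug_mask & event).sum()),
        b=int((drug_mask & ~event).sum()),
        c=int((ref_mask & event).sum()),
        d=int((ref_mask & ~event).sum()),
        exposure_label=f"{drug} vs {reference}",
        event_label=event_label,
    )
    return ror(table), table
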