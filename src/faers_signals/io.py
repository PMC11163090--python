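"""Reading, validating, linking and writing FAERS-schema quarterly ASCII tables.

The FDA publishes FAERS as quarterly bundles of "$"-delimited ASCII files
(DEMO, DRUG, REAC, OUTC, plus a DELETED list of invalidated reports). Each
file has a single header row; fields are never quoted and the dialect has no
escape convention. This module reads those files into typed pandas frames,
applies the DELETED list, and writes the same dialect back out losslessly.

Case versioning (``caseid``/``caseversion``) is preserved here; collapsing a
case's versions is the cohort builder's job, which keeps this layer lossless.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from io import StringIO
from pathlib import Path

import numpy as np
import pandas as pd

from .utils import format_faers_date, parse_faers_dates

__all__ = [
    "SchemaError",
    "QuarterBundle",
    "read_ascii_table",
    "load_quarter_bundle",
    "apply_deletions",
    "write_normalized",
    "TABLE_KINDS",
]

DELIM = "$"

TABLE_KINDS = ("DEMO", "DRUG", "REAC", "OUTC", "DELETED")
CORE_KINDS = ("DEMO", "DRUG", "REAC", "OUTC")

#: Columns a table of each kind must provide (our normalized FAERS dialect).
MANDATORY_COLUMNS = {
    "DEMO": ["primaryid", "caseid", "caseversion", "event_dt", "fda_dt",
             "age", "age_cod", "sex"],
    "DRUG": ["primaryid", "drug_seq", "role_cod", "drugname"],
    "REAC": ["primaryid", "pt"],
    "OUTC": ["primaryid", "outc_cod"],
    "DELETED": ["primaryid"],
}

#: Recognized optional columns; added (all-missing) when absent from a file.
OPTIONAL_COLUMNS = {
    "DEMO": ["occr_country", "reporter_country"],
    "DRUG": ["prod_ai"],
    "REAC": [],
    "OUTC": [],
    "DELETED": [],
}


class SchemaError(ValueError):
    """A FAERS table file does not conform to the expected schema."""


@dataclass(frozen=True)
class QuarterBundle:
    """One FAERS quarter: the four core tables plus the deletion list.

    After :func:`apply_deletions` no record in any table carries a
    ``primaryid`` present in ``deleted_primaryids``.
    """

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    outc: pd.DataFrame
    deleted_primaryids: frozenset = field(default_factory=frozenset)
    quarter_label: str = ""

    @property
    def n_reports(self) -> int:
        return len(self.demo)

    def tables(self) -> dict[str, pd.DataFrame]:
        return {"DEMO": self.demo, "DRUG": self.drug,
                "REAC": self.reac, "OUTC": self.outc}


def _decode(path: Path) -> str:
    data = Path(path).read_bytes()
    try:
        return data.decode("utf-8")
    except UnicodeDecodeError:
        return data.decode("latin-1")


def _coerce_string(df: pd.DataFrame, cols) -> None:
    for col in cols:
        df[col] = df[col].astype("string").str.strip().replace("", pd.NA)


def _coerce_int(df: pd.DataFrame, col: str, fill=None) -> None:
    df[col] = pd.to_numeric(df[col], errors="coerce").astype("Int64")
    if fill is not None:
        df[col] = df[col].fillna(fill)


def _coerce_upper(df: pd.DataFrame, col: str) -> None:
    df[col] = df[col].astype("string").str.strip().str.upper().replace("", pd.NA)


def read_ascii_table(path, table_kind: str) -> pd.DataFrame:
    """Read one "$"-delimited FAERS table into a typed DataFrame.

    Parameters
    ----------
    path : path-like
        File whose first line is a "$"-delimited header.
    table_kind : {"DEMO", "DRUG", "REAC", "OUTC", "DELETED"}

    Returns
    -------
    DataFrame with one row per non-blank data line. Mandatory columns are
    typed (identifiers as strings, ``caseversion``/``drug_seq`` as nullable
    ints, dates parsed, codes upper-cased); unknown extra columns are kept
    verbatim as opaque string columns. Unparseable dates are set missing and
    reported through a single aggregated warning, never an error.

    Raises
    ------
    SchemaError
        If the header lacks a mandatory column for ``table_kind``.
    """
    kind = table_kind.upper()
    if kind not in MANDATORY_COLUMNS:
        raise ValueError(f"unknown table kind {table_kind!r}")
    text = _decode(Path(path))
    df = pd.read_csv(
        StringIO(text),
        sep=DELIM,
        dtype="string",
        skip_blank_lines=True,
        keep_default_na=False,
        na_values=[""],
    )
    df.columns = [str(c).strip().lower() for c in df.columns]
    missing = [c for c in MANDATORY_COLUMNS[kind] if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{kind} table {path} is missing mandatory column(s): {', '.join(missing)}"
        )
    for col in OPTIONAL_COLUMNS[kind]:
        if col not in df.columns:
            df[col] = pd.Series(pd.NA, index=df.index, dtype="string")

    _coerce_string(df, ["primaryid"])
    if kind == "DEMO":
        _coerce_string(df, ["caseid", "occr_country", "reporter_country"])
        _coerce_int(df, "caseversion", fill=1)
        n_bad = 0
        for col in ("event_dt", "fda_dt"):
            df[col], bad = parse_faers_dates(df[col])
            n_bad += bad
        if n_bad:
            warnings.warn(
                f"{path}: {n_bad} unparseable date value(s) set to missing",
                stacklevel=2,
            )
        df["age"] = pd.to_numeric(df["age"], errors="coerce").astype(float)
        df.loc[df["age"] < 0, "age"] = np.nan
        _coerce_upper(df, "age_cod")
        # age and its unit travel together: drop whichever is orphaned
        orphan = df["age"].isna() ^ df["age_cod"].isna()
        df.loc[orphan, "age"] = np.nan
        df.loc[orphan, "age_cod"] = pd.NA
        _coerce_upper(df, "sex")
        df["sex"] = df["sex"].replace({"UNK": pd.NA})
    elif kind == "DRUG":
        _coerce_int(df, "drug_seq")
        _coerce_upper(df, "role_cod")
        _coerce_string(df, ["drugname", "prod_ai"])
    elif kind == "REAC":
        _coerce_string(df, ["pt"])
    elif kind == "OUTC":
        _coerce_upper(df, "outc_cod")

    # canonical column order: mandatory, optional, then extras in file order
    known = MANDATORY_COLUMNS[kind] + OPTIONAL_COLUMNS[kind]
    extras = [c for c in df.columns if c not in known]
    return df[known + extras]


def apply_deletions(bundle: QuarterBundle) -> QuarterBundle:
    """Drop every record whose primaryid is on the bundle's DELETED list.

    Idempotent; a bundle with an empty deletion set is returned unchanged.
    """
    if not bundle.deleted_primaryids:
        return bundle
    dropped = {str(x) for x in bundle.deleted_primaryids}

    def _filter(df: pd.DataFrame) -> pd.DataFrame:
        keep = ~df["primaryid"].astype("string").isin(dropped)
        return df.loc[keep].reset_index(drop=True)

    return replace(
        bundle,
        demo=_filter(bundle.demo),
        drug=_filter(bundle.drug),
        reac=_filter(bundle.reac),
        outc=_filter(bundle.outc),
    )


def _find_table_file(directory: Path, kind: str, quarter_label: str) -> Path | None:
    exact = directory / f"{kind}{quarter_label}.txt"
    if exact.exists():
        return exact
    candidates = sorted(
        p for p in directory.iterdir()
        if p.is_file() and p.name.upper().startswith(kind) and p.suffix.lower() == ".txt"
    )
    return candidates[0] if candidates else None


def load_quarter_bundle(directory, quarter_label: str) -> QuarterBundle:
    """Load a quarter's DEMO/DRUG/REAC/OUTC (+ optional DELETED) files.

    Files are looked up as ``<KIND><quarter_label>.txt`` first, then by kind
    prefix. Deletions are applied before the bundle is returned.

    Raises
    ------
    FileNotFoundError
        Naming the missing core table if one of DEMO/DRUG/REAC/OUTC is absent.
    """
    directory = Path(directory)
    tables = {}
    for kind in CORE_KINDS:
        path = _find_table_file(directory, kind, quarter_label)
        if path is None:
            raise FileNotFoundError(
                f"no {kind} table found in {directory} for quarter {quarter_label}"
            )
        tables[kind] = read_ascii_table(path, kind)
    deleted_path = _find_table_file(directory, "DELETED", quarter_label)
    deleted: frozenset = frozenset()
    if deleted_path is not None:
        deleted_df = read_ascii_table(deleted_path, "DELETED")
        deleted = frozenset(deleted_df["primaryid"].dropna().astype(str))
    bundle = QuarterBundle(
        demo=tables["DEMO"],
        drug=tables["DRUG"],
        reac=tables["REAC"],
        outc=tables["OUTC"],
        deleted_primaryids=deleted,
        quarter_label=quarter_label,
    )
    dup = bundle.demo["primaryid"].duplicated()
    if dup.any():
        warnings.warn(
            f"{quarter_label}: {int(dup.sum())} duplicated primaryid(s) in DEMO",
            stacklevel=2,
        )
    return apply_deletions(bundle)


def _format_cell(value) -> str:
    if pd.isna(value):
        return ""
    if isinstance(value, pd.Timestamp):
        return format_faers_date(value)
    if isinstance(value, (float, np.floating)):
        return format(value, ".12g")
    if isinstance(value, (int, np.integer)):
        return str(int(value))
    return str(value)


def _serialize_table(df: pd.DataFrame, delim_substitute: str) -> str:
    if df.empty:
        return DELIM.join(df.columns) + "\n"
    out = df.copy()
    n_dollar = 0
    for col in out.columns:
        cells = out[col].map(_format_cell)
        hit = cells.str.contains(DELIM, regex=False)
        if hit.any():
            n_dollar += int(hit.sum())
            cells = cells.str.replace(DELIM, delim_substitute, regex=False)
        out[col] = cells
    if n_dollar:
        warnings.warn(
            f"{n_dollar} field value(s) contained the '$' delimiter and were "
            f"rewritten with {delim_substitute!r}",
            stacklevel=3,
        )
    lines = [DELIM.join(out.columns)]
    lines.extend(DELIM.join(row) for row in out.itertuples(index=False, name=None))
    return "\n".join(lines) + "\n"


def write_normalized(bundle: QuarterBundle, directory, *, delim_substitute: str = "") -> dict[str, Path]:
    """Write a bundle back to "$"-delimited files, one per table kind.

    The written files round-trip: reading them with :func:`read_ascii_table`
    reproduces the typed representation field-for-field. Native FAERS has no
    escape convention for an embedded "$"; offending characters are replaced
    by ``delim_substitute`` (default: stripped) with a warning.

    Returns the mapping of table kind to the file written. A DELETED file is
    written whenever the bundle carries deletion ids.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    label = bundle.quarter_label
    written: dict[str, Path] = {}
    for kind, df in bundle.tables().items():
        path = directory / f"{kind}{label}.txt"
        path.write_text(_serialize_table(df, delim_substitute), encoding="utf-8")
        written[kind] = path
    if bundle.deleted_primaryids:
        path = directory / f"DELETED{label}.txt"
        rows = "\n".join(sorted(bundle.deleted_primaryids))
        path.write_text("primaryid\n" + rows + "\n", encoding="utf-8")
        written["DELETED"] = path
    return written
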