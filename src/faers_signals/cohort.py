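"""Build the analysis cohort from raw quarter bundles.

The pipeline here mirrors the standard spontaneous-report cleaning sequence:

1. deduplicate (latest case version per case, then collapse reports that are
   identical on case / event date / reaction terms),
2. restrict to the study window by report year,
3. keep primary-suspect (PS) drug exposures and map them to drug classes,
4. flag whether the target adverse-event preferred term (PT) is present.

Every step's exclusion count is recorded in an audit mapping so that
``input = output + Σ exclusions`` always holds.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import QuarterBundle
from .utils import age_to_years, bin_age_years, normalize_term

__all__ = [
    "DrugClassMap",
    "FilterConfig",
    "default_class_map",
    "deduplicate_reports",
    "filter_window",
    "map_drug_classes",
    "flag_event",
    "build_cohort",
]

_MISSING_KEY = "\x00missing"


class ClassMapError(ValueError):
    """The drug-class dictionary is empty or inconsistent."""


@dataclass(frozen=True)
class DrugClassMap:
    """Dictionary mapping drug names (generic and brand) to drug classes.

    ``entries`` is a frame with columns ``class_name``, ``drug_name``,
    ``is_reference``. A drug name may belong to at most one class and each
    class has at most one reference drug (used for within-class comparisons).
    """

    entries: pd.DataFrame

    def __post_init__(self):
        df = self.entries
        required = {"class_name", "drug_name", "is_reference"}
        if df.empty or not required.issubset(df.columns):
            raise ClassMapError(
                "drug-class map must be non-empty with columns "
                "class_name, drug_name, is_reference"
            )
        norm = df["drug_name"].map(normalize_term)
        dup = norm[norm.duplicated()]
        multi = df.assign(_n=norm).groupby("_n")["class_name"].nunique()
        if (multi > 1).any():
            bad = multi[multi > 1].index.tolist()
            raise ClassMapError(f"drug name(s) mapped to more than one class: {bad}")
        refs = df[df["is_reference"].astype(bool)].groupby("class_name").size()
        if (refs > 1).any():
            raise ClassMapError("a class has more than one reference drug")
        object.__setattr__(self, "_lookup",
                           dict(zip(norm, df["class_name"])))
        object.__setattr__(self, "_references",
                           {row.class_name: row.drug_name
                            for row in df[df["is_reference"].astype(bool)].itertuples()})

    @property
    def classes(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self.entries["class_name"]))

    def class_of(self, drug_name) -> str | None:
        return self._lookup.get(normalize_term(drug_name))

    def reference_drug(self, class_name: str) -> str | None:
        return self._references.get(class_name)

    @classmethod
    def from_file(cls, path) -> "DrugClassMap":
        df = pd.read_csv(path, sep="\t", dtype={"class_name": str, "drug_name": str})
        df["is_reference"] = df["is_reference"].astype(int).astype(bool)
        return cls(df)


def default_class_map() -> DrugClassMap:
    """The shipped antidiabetic dictionary: GLP-1 RA, DPP-4 and SGLT2
    inhibitors with US brand names; exenatide is the GLP-1 RA reference."""
    ref = importlib.resources.files("faers_signals.data") / "drug_classes.tsv"
    with importlib.resources.as_file(ref) as path:
        return DrugClassMap.from_file(path)


@dataclass(frozen=True)
class FilterConfig:
    """Cohort inclusion settings: study window, target PT, dedup semantics."""

    year_min: int = 2019
    year_max: int = 2021
    target_pt: str = "pancreatitis"
    dedup_mode: str = "two_stage"  # or "literal"

    def __post_init__(self):
        if self.year_min > self.year_max:
            raise ValueError("year_min must be <= year_max")
        if not normalize_term(self.target_pt):
            raise ValueError("target_pt must be non-empty")
        if self.dedup_mode not in {"two_stage", "literal"}:
            raise ValueError(f"unknown dedup_mode {self.dedup_mode!r}")


def _pt_sets(reac: pd.DataFrame) -> pd.Series:
    """Sorted tuple of normalized PTs per primaryid (duplicates dropped)."""
    pts = reac[["primaryid", "pt"]].copy()
    pts["pt"] = pts["pt"].map(normalize_term)
    pts = pts.dropna(subset=["pt"]).drop_duplicates()
    return pts.groupby("primaryid")["pt"].agg(lambda s: tuple(sorted(s)))


def _concat(bundles: list[QuarterBundle], attr: str) -> pd.DataFrame:
    frames = [getattr(b, attr) for b in bundles]
    frames = [f for f in frames if not f.empty]
    if not frames:
        return getattr(bundles[0], attr).iloc[0:0].copy()
    return pd.concat(frames, ignore_index=True)


def deduplicate_reports(
    bundles: list[QuarterBundle], mode: str = "two_stage"
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Collapse duplicate spontaneous reports across quarters.

    Two-stage rule (default): (i) within each ``caseid`` keep only the rows at
    the highest ``caseversion``; (ii) collapse rows identical on
    (caseid, event_dt, PT set), keeping the largest primaryid; a residual
    same-case collapse then guarantees one record per caseid. In
    ``"literal"`` mode only exact (primaryid, event_dt, PT set)
    duplicates are dropped and case versions are all retained.

    Returns the retained DEMO rows (with a ``pts`` tuple column attached,
    sorted by primaryid so the result is independent of bundle order) and an
    audit dict with ``version_collapsed`` / ``duplicate_collapsed`` counts.
    Idempotent: re-running on its own output removes nothing.
    """
    demo = _concat(bundles, "demo")
    reac = _concat(bundles, "reac")
    pts = _pt_sets(reac)
    demo = demo.copy()
    demo["pts"] = demo["primaryid"].map(pts)
    demo["pts"] = demo["pts"].apply(lambda v: v if isinstance(v, tuple) else ())
    demo = demo.sort_values("primaryid", kind="stable").reset_index(drop=True)
    n_in = len(demo)

    audit = {"input_reports": n_in, "version_collapsed": 0, "duplicate_collapsed": 0}
    if demo.empty:
        return demo, audit

    date_key = demo["event_dt"].map(
        lambda v: _MISSING_KEY if pd.isna(v) else pd.Timestamp(v).strftime("%Y%m%d")
    )
    if mode == "literal":
        keep = ~pd.DataFrame(
            {"primaryid": demo["primaryid"], "dt": date_key, "pts": demo["pts"]}
        ).duplicated()
        audit["duplicate_collapsed"] = int((~keep).sum())
        return demo.loc[keep].reset_index(drop=True), audit

    # (i) latest caseversion per caseid
    case_key = demo["caseid"].fillna(demo["primaryid"])
    max_version = demo.groupby(case_key)["caseversion"].transform("max")
    stage1 = demo["caseversion"] == max_version
    audit["version_collapsed"] = int((~stage1).sum())
    demo = demo.loc[stage1]
    date_key = date_key.loc[demo.index]

    # (ii) collapse identical (caseid, event_dt, pts); keep largest primaryid
    key = pd.DataFrame({
        "caseid": demo["caseid"].fillna(demo["primaryid"]),
        "dt": date_key.values,
        "pts": demo["pts"].values,
    }, index=demo.index)
    keep2 = ~key.duplicated(keep="last")
    n2 = int((~keep2).sum())
    demo = demo.loc[keep2]

    # residual: duplicate copies of a case differing on date/PTs
    keep3 = ~demo["caseid"].fillna(demo["primaryid"]).duplicated(keep="last")
    n3 = int((~keep3).sum())
    demo = demo.loc[keep3]
    audit["duplicate_collapsed"] = n2 + n3
    return demo.reset_index(drop=True), audit


def _derive_report_year(demo: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Report year from event_dt, else fda_dt; also which source was used."""
    event_year = demo["event_dt"].dt.year
    fda_year = demo["fda_dt"].dt.year
    year = event_year.fillna(fda_year)
    source = pd.Series(
        np.where(event_year.notna(), "event_dt",
                 np.where(fda_year.notna(), "fda_dt", "missing")),
        index=demo.index,
    )
    return year.astype("Int64"), source


def filter_window(
    records: pd.DataFrame, config: FilterConfig
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Keep records whose report year lies in [year_min, year_max].

    Records with no derivable year (both dates missing) are excluded — the
    window is an inclusion criterion — and tallied separately from
    out-of-window exclusions.
    """
    records = records.copy()
    if "report_year" not in records.columns:
        records["report_year"], records["year_source"] = _derive_report_year(records)
    missing = records["report_year"].isna()
    in_window = (
        ~missing
        & (records["report_year"] >= config.year_min)
        & (records["report_year"] <= config.year_max)
    )
    audit = {
        "missing_year_excluded": int(missing.sum()),
        "out_of_window_excluded": int((~in_window & ~missing).sum()),
    }
    return records.loc[in_window].reset_index(drop=True), audit


def map_drug_classes(ps_names, class_map: DrugClassMap) -> frozenset:
    """Classes whose members match any primary-suspect drug name/ingredient.

    Matching is normalized (case/whitespace-insensitive) and exact on the
    full name; non-PS roles must not be passed in.
    """
    if class_map is None or class_map.entries.empty:
        raise ClassMapError("drug-class map is empty")
    hits = {class_map.class_of(name) for name in ps_names}
    hits.discard(None)
    return frozenset(hits)


def flag_event(pts, target_pt: str, extra_terms=()) -> bool:
    """True iff the target PT matches one of the report's PTs exactly.

    Exact (normalized) matching: "pancreatitis acute" does not match target
    "pancreatitis". ``extra_terms`` supports an opt-in term-list mode.
    """
    targets = {normalize_term(target_pt)} | {normalize_term(t) for t in extra_terms}
    targets.discard(None)
    return any(normalize_term(pt) in targets for pt in pts)


def _ps_drug_sets(drug: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    ps = drug.loc[drug["role_cod"] == "PS", ["primaryid", "drugname", "prod_ai"]]
    names = ps.assign(name=ps["drugname"].map(normalize_term)).dropna(subset=["name"])
    ingredients = ps.assign(name=ps["prod_ai"].map(normalize_term)).dropna(subset=["name"])
    agg = lambda s: frozenset(s)
    return (
        names.groupby("primaryid")["name"].agg(agg),
        ingredients.groupby("primaryid")["name"].agg(agg),
    )


def build_cohort(
    bundles: list[QuarterBundle],
    config: FilterConfig,
    class_map: DrugClassMap,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Run dedup → window filter → PS class mapping → event flagging.

    Returns
    -------
    cohort : DataFrame
        One row per case with columns ``caseid, primaryid, event_flag,
        ps_drugs, drug_classes, pts, sex, age_years, age_bin, report_year,
        year_source, country, outcome_codes``.
    audit : dict
        Per-step exclusion tallies satisfying
        ``input_reports == len(cohort) + Σ exclusions``, plus a
        ``multi_class_reports`` informational count.
    """
    demo, audit = deduplicate_reports(bundles, config.dedup_mode)
    demo, window_audit = filter_window(demo, config)
    audit.update(window_audit)

    drug = _concat(bundles, "drug")
    outc = _concat(bundles, "outc")
    ps_names, ps_ingredients = _ps_drug_sets(drug)
    outcome_sets = (
        outc.dropna(subset=["outc_cod"])
        .drop_duplicates()
        .groupby("primaryid")["outc_cod"]
        .agg(lambda s: frozenset(s))
    )

    empty = frozenset()
    cohort = pd.DataFrame({
        "caseid": demo["caseid"].fillna(demo["primaryid"]),
        "primaryid": demo["primaryid"],
        "pts": demo["pts"],
        "sex": demo["sex"],
        "report_year": demo["report_year"].astype(int),
        "year_source": demo["year_source"],
        "country": demo["occr_country"].fillna(demo["reporter_country"]),
    })
    cohort["ps_drugs"] = demo["primaryid"].map(ps_names).apply(
        lambda v: v if isinstance(v, frozenset) else empty)
    ingredients = demo["primaryid"].map(ps_ingredients).apply(
        lambda v: v if isinstance(v, frozenset) else empty)
    cohort["drug_classes"] = [
        map_drug_classes(names | ingr, class_map)
        for names, ingr in zip(cohort["ps_drugs"], ingredients)
    ]
    cohort["event_flag"] = [
        flag_event(pts, config.target_pt) for pts in cohort["pts"]
    ]
    cohort["age_years"] = [
        age_to_years(a, u) for a, u in zip(demo["age"], demo["age_cod"])
    ]
    cohort["age_bin"] = bin_age_years(pd.Series(cohort["age_years"]))
    cohort["outcome_codes"] = demo["primaryid"].map(outcome_sets).apply(
        lambda v: v if isinstance(v, frozenset) else empty)

    audit["multi_class_reports"] = int(
        sum(len(c) > 1 for c in cohort["drug_classes"])
    )
    audit["final_cohort"] = len(cohort)
    return cohort.reset_index(drop=True), audit
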