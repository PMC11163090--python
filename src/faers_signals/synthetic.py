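"""Synthetic FAERS-schema data with known ground truth.

The generator draws a drug x event count grid from a Poisson independence
model with multiplicative relative-risk signals injected at chosen pairs:

    count(i, j) ~ Poisson( N * w_drug[i] * w_event[j] * rr(i, j) )

with rr = 1 everywhere off the injected list. Each count is expanded into a
spontaneous-report case with demographics, one primary-suspect drug, one
reaction PT and outcome codes, and the usual FAERS warts are layered on:
duplicate report copies, re-submitted case versions, and missing
sex/age/date fields — all at configurable rates, all recorded in the
returned ground truth, and all fully reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import QuarterBundle

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_database",
    "truth_table",
    "preset",
    "PRESETS",
]

_OUTCOME_CODES = np.array(["HO", "OT", "DE", "LT", "DS", "RI", "CA"])
_OUTCOME_PROBS = np.array([0.40, 0.28, 0.07, 0.06, 0.05, 0.04, 0.10])
_COUNTRIES = np.array(["US", "GB", "JP", "FR", "DE", "CA"])
_COUNTRY_PROBS = np.array([0.70, 0.08, 0.07, 0.05, 0.05, 0.05])


@dataclass(frozen=True)
class SyntheticConfig:
    """Everything the generator needs; the seed is mandatory.

    Margin weights may be ``None`` (uniform, with the injected drug's weight
    multiplied by ``injected_margin_boost`` so the headline injected pair
    sits at a controlled expected count), the string ``"dirichlet"`` for a
    seeded symmetric Dirichlet draw, or an explicit sequence of positive
    weights.
    """

    seed: int
    n_drugs: int = 200
    n_events: int = 100
    n_reports: int = 200_000
    drug_margin_weights: object = None
    event_margin_weights: object = None
    injected_signals: tuple = (("DRUG_001", "EVENT_001", 10.0),)
    injected_margin_boost: float = 2.0
    duplicate_rate: float = 0.02
    version_rate: float = 0.02
    missing_sex_rate: float = 0.05
    missing_date_rate: float = 0.05
    missing_both_dates_rate: float = 0.0
    missing_age_rate: float = 0.10
    year_range: tuple = (2019, 2021)
    study_window: tuple = (2019, 2021)  # window the ground-truth tallies use
    outcome_any_rate: float = 0.70
    multi_drug_rate: float = 0.0
    multi_pt_rate: float = 0.0

    def __post_init__(self):
        rates = (self.duplicate_rate, self.version_rate, self.missing_sex_rate,
                 self.missing_date_rate, self.missing_both_dates_rate,
                 self.missing_age_rate, self.outcome_any_rate,
                 self.multi_drug_rate, self.multi_pt_rate)
        if any(not (0.0 <= r <= 1.0) for r in rates):
            raise ValueError("all rates must lie in [0, 1]")
        if self.seed is None:
            raise ValueError("seed is mandatory (no hidden entropy)")
        names = {f"DRUG_{i + 1:03d}" for i in range(self.n_drugs)}
        events = {f"EVENT_{j + 1:03d}" for j in range(self.n_events)}
        for drug, event, rr in self.injected_signals:
            if drug not in names or event not in events:
                raise ValueError(f"injected pair ({drug}, {event}) outside the grid")
            if rr <= 0:
                raise ValueError("injected relative risks must be positive")

    def drug_names(self) -> list[str]:
        return [f"DRUG_{i + 1:03d}" for i in range(self.n_drugs)]

    def event_names(self) -> list[str]:
        return [f"EVENT_{j + 1:03d}" for j in range(self.n_events)]


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually did, joinable to pipeline outputs."""

    config: SyntheticConfig
    pair_table: pd.DataFrame  # drug, event, true_rr, e_null, n_cases
    case_table: pd.DataFrame  # per unique case, demographics as drawn
    n_unique_cases: int
    n_duplicates: int
    n_versions: int
    in_window_cases: int
    out_of_window_cases: int
    missing_year_cases: int


def _resolve_weights(spec, size, rng, boost_idx=None, boost=1.0):
    if spec is None:
        w = np.ones(size)
        if boost_idx is not None:
            w[boost_idx] *= boost
    elif isinstance(spec, str) and spec == "dirichlet":
        w = rng.dirichlet(np.full(size, 5.0))
    else:
        w = np.asarray(spec, dtype=float)
        if w.shape != (size,) or np.any(w <= 0):
            raise ValueError("margin weights must be positive with one entry per label")
    return w / w.sum()


def generate_database(config: SyntheticConfig) -> tuple[list[QuarterBundle], GroundTruth]:
    """Draw the grid, expand to FAERS-schema quarter bundles, return truth."""
    rng = np.random.default_rng(config.seed)
    drugs = np.array(config.drug_names())
    events = np.array(config.event_names())
    drug_index = {d: i for i, d in enumerate(drugs)}
    event_index = {e: j for j, e in enumerate(events)}

    boost_idx = (
        drug_index[config.injected_signals[0][0]] if config.injected_signals else None
    )
    wd = _resolve_weights(config.drug_margin_weights, config.n_drugs, rng,
                          boost_idx, config.injected_margin_boost)
    we = _resolve_weights(config.event_margin_weights, config.n_events, rng)

    rr = np.ones((config.n_drugs, config.n_events))
    for drug, event, value in config.injected_signals:
        rr[drug_index[drug], event_index[event]] = value
    e_null = config.n_reports * np.outer(wd, we)
    counts = rng.poisson(e_null * rr)
    n_cases = int(counts.sum())

    # one case per count, shuffled so caseid order carries no grid structure
    pair_idx = np.repeat(np.arange(counts.size), counts.ravel())
    rng.shuffle(pair_idx)
    d_idx, e_idx = np.unravel_index(pair_idx, counts.shape)

    case_num = np.arange(1, n_cases + 1)
    caseid = np.char.add("SYN", np.char.zfill(case_num.astype(str), 8))

    y0, y1 = config.year_range
    years = rng.integers(y0, y1 + 1, n_cases)
    day_of_year = rng.integers(0, 365, n_cases)
    event_dt = pd.to_datetime(
        pd.DataFrame({"year": years, "month": 1, "day": 1})
    ) + pd.to_timedelta(day_of_year, unit="D")
    lag = rng.geometric(1 / 30.0, n_cases)  # event precedes submission
    fda_dt = event_dt + pd.to_timedelta(lag, unit="D")

    sex = np.where(rng.random(n_cases) < 0.5, "F", "M")
    sex = pd.Series(sex, dtype="string").mask(rng.random(n_cases) < config.missing_sex_rate)
    age_years = np.clip(rng.normal(58, 15, n_cases), 1, 100)
    age_cod = pd.Series(np.full(n_cases, "YR"), dtype="string")
    in_months = rng.random(n_cases) < 0.05
    age = age_years.copy()
    age[in_months] = np.round(age_years[in_months] * 12)
    age_cod[in_months] = "MON"
    age = np.round(age, 1)
    missing_age = rng.random(n_cases) < config.missing_age_rate
    age = pd.Series(age).mask(missing_age)
    age_cod = age_cod.mask(missing_age)
    country = pd.Series(
        rng.choice(_COUNTRIES, n_cases, p=_COUNTRY_PROBS), dtype="string"
    )

    miss_event_dt = rng.random(n_cases) < config.missing_date_rate
    miss_both = rng.random(n_cases) < config.missing_both_dates_rate
    event_dt = pd.Series(event_dt).mask(miss_event_dt | miss_both)
    fda_dt = pd.Series(fda_dt).mask(miss_both)

    has_outcome = rng.random(n_cases) < config.outcome_any_rate
    has_second = has_outcome & (rng.random(n_cases) < 0.10)
    code1 = rng.choice(_OUTCOME_CODES, size=n_cases, p=_OUTCOME_PROBS)
    code2 = rng.choice(_OUTCOME_CODES, size=n_cases, p=_OUTCOME_PROBS)
    outcome_sets = [
        tuple(sorted({code1[i], code2[i]})) if has_second[i] and code2[i] != code1[i]
        else ((code1[i],) if has_outcome[i] else ())
        for i in range(n_cases)
    ]

    cases = pd.DataFrame({
        "caseid": caseid,
        "drug": drugs[d_idx],
        "event": events[e_idx],
        "event_dt": event_dt,
        "fda_dt": fda_dt,
        "sex": sex,
        "age": age,
        "age_cod": age_cod,
        "country": country,
        "outcomes": outcome_sets,
    })

    # ground-truth report_year mirrors the cohort rule: event year, else fda year
    report_year = cases["event_dt"].dt.year.fillna(cases["fda_dt"].dt.year)
    missing_year = int(report_year.isna().sum())
    w0, w1 = config.study_window
    in_window = int(((report_year >= w0) & (report_year <= w1)).sum())
    out_of_window = n_cases - in_window - missing_year

    # secondary drugs / extra PTs (off by default; exercises multi-exposure logic)
    extra_drug = rng.random(n_cases) < config.multi_drug_rate
    extra_drug_name = drugs[rng.integers(0, config.n_drugs, n_cases)]
    extra_pt = rng.random(n_cases) < config.multi_pt_rate
    extra_pt_name = events[rng.integers(0, config.n_events, n_cases)]

    # duplicate and version re-emissions: disjoint case subsets
    order = rng.permutation(n_cases)
    n_dup = int(round(config.duplicate_rate * n_cases))
    n_ver = int(round(config.version_rate * n_cases))
    dup_rows = np.sort(order[:n_dup])
    ver_rows = np.sort(order[n_dup:n_dup + n_ver])

    def _emit(rows: pd.DataFrame, caseversion: np.ndarray, copy_tag: str):
        pid = rows["caseid"].str.replace("SYN", "", regex=False) + \
            pd.Series(caseversion.astype(str), index=rows.index) + copy_tag
        demo = pd.DataFrame({
            "primaryid": pid.astype("string"),
            "caseid": rows["caseid"].astype("string"),
            "caseversion": pd.array(caseversion, dtype="Int64"),
            "event_dt": rows["event_dt"],
            "fda_dt": rows["fda_dt"],
            "age": rows["age"].astype(float),
            "age_cod": rows["age_cod"],
            "sex": rows["sex"],
            "occr_country": rows["country"],
            "reporter_country": rows["country"],
        })
        drug_parts = [pd.DataFrame({
            "primaryid": pid.astype("string"),
            "drug_seq": pd.array(np.ones(len(rows), dtype=int), dtype="Int64"),
            "role_cod": pd.Series("PS", index=rows.index, dtype="string"),
            "drugname": rows["drug"].astype("string"),
            "prod_ai": pd.Series(pd.NA, index=rows.index, dtype="string"),
        })]
        sel = rows["_extra_drug"].to_numpy(bool)
        if sel.any():
            sub = rows.loc[sel]
            drug_parts.append(pd.DataFrame({
                "primaryid": pid[sel].astype("string"),
                "drug_seq": pd.array(np.full(sel.sum(), 2), dtype="Int64"),
                "role_cod": pd.Series("SS", index=sub.index, dtype="string"),
                "drugname": sub["_extra_drug_name"].astype("string"),
                "prod_ai": pd.Series(pd.NA, index=sub.index, dtype="string"),
            }))
        drug = pd.concat(drug_parts, ignore_index=True)
        reac_parts = [pd.DataFrame({
            "primaryid": pid.astype("string"),
            "pt": rows["event"].astype("string"),
        })]
        sel = rows["_extra_pt"].to_numpy(bool)
        if sel.any():
            sub = rows.loc[sel]
            reac_parts.append(pd.DataFrame({
                "primaryid": pid[sel].astype("string"),
                "pt": sub["_extra_pt_name"].astype("string"),
            }))
        reac = pd.concat(reac_parts, ignore_index=True).drop_duplicates()
        outc_records = [
            (p, code)
            for p, codes in zip(pid, rows["outcomes"])
            for code in codes
        ]
        outc = pd.DataFrame(outc_records, columns=["primaryid", "outc_cod"]).astype(
            {"primaryid": "string", "outc_cod": "string"}
        )
        return demo, drug, reac, outc

    cases["_extra_drug"] = extra_drug
    cases["_extra_drug_name"] = extra_drug_name
    cases["_extra_pt"] = extra_pt
    cases["_extra_pt_name"] = extra_pt_name

    ones = np.ones(n_cases, dtype=int)
    demo0, drug0, reac0, outc0 = _emit(cases, ones, "0")
    parts_demo, parts_drug, parts_reac, parts_outc = [demo0], [drug0], [reac0], [outc0]
    if n_dup:
        dups = cases.iloc[dup_rows]
        d, dr, re_, oc = _emit(dups, np.ones(len(dups), dtype=int), "1")
        parts_demo.append(d); parts_drug.append(dr); parts_reac.append(re_); parts_outc.append(oc)
    if n_ver:
        vers = cases.iloc[ver_rows]
        d, dr, re_, oc = _emit(vers, np.full(len(vers), 2, dtype=int), "0")
        parts_demo.append(d); parts_drug.append(dr); parts_reac.append(re_); parts_outc.append(oc)

    demo = pd.concat(parts_demo, ignore_index=True)
    drug = pd.concat(parts_drug, ignore_index=True)
    reac = pd.concat(parts_reac, ignore_index=True)
    outc = pd.concat(parts_outc, ignore_index=True)

    # split into quarterly bundles on the submission (fda) date
    quarter = demo["fda_dt"].dt.year.astype("Int64").astype("string") + "Q" + \
        demo["fda_dt"].dt.quarter.astype("Int64").astype("string")
    quarter = quarter.fillna(f"{y0}Q1")  # undated reports land in the first quarter
    bundles = []
    for label in sorted(quarter.unique()):
        pids = set(demo.loc[quarter == label, "primaryid"])
        sel = lambda df: df[df["primaryid"].isin(pids)].reset_index(drop=True)
        bundles.append(QuarterBundle(
            demo=sel(demo), drug=sel(drug), reac=sel(reac), outc=sel(outc),
            deleted_primaryids=frozenset(), quarter_label=str(label),
        ))

    pair_table = pd.DataFrame({
        "drug": np.repeat(drugs, config.n_events),
        "event": np.tile(events, config.n_drugs),
        "true_rr": rr.ravel(),
        "e_null": e_null.ravel(),
        "n_cases": counts.ravel(),
    })
    truth = GroundTruth(
        config=config,
        pair_table=pair_table,
        case_table=cases.drop(
            columns=["_extra_drug", "_extra_drug_name", "_extra_pt", "_extra_pt_name"]
        ),
        n_unique_cases=n_cases,
        n_duplicates=n_dup,
        n_versions=n_ver,
        in_window_cases=in_window,
        out_of_window_cases=out_of_window,
        missing_year_cases=missing_year,
    )
    return bundles, truth


def truth_table(ground_truth: GroundTruth) -> pd.DataFrame:
    """One row per drug x event pair: true relative risk and expectations."""
    return ground_truth.pair_table.copy()


PRESETS = {
    "null": dict(
        n_drugs=50, n_events=40, n_reports=50_000,
        injected_signals=(), injected_margin_boost=1.0,
        duplicate_rate=0.0, version_rate=0.0,
        missing_sex_rate=0.0, missing_date_rate=0.0, missing_age_rate=0.0,
    ),
    "headline": dict(),  # the defaults above are the headline scenario
    "stress": dict(
        n_drugs=100, n_events=50, n_reports=50_000,
        year_range=(2018, 2022),
        duplicate_rate=0.05, version_rate=0.05,
        missing_sex_rate=0.15, missing_date_rate=0.15,
        missing_both_dates_rate=0.02, missing_age_rate=0.25,
        multi_drug_rate=0.10, multi_pt_rate=0.10,
        injected_signals=(("DRUG_007", "EVENT_003", 10.0),),
    ),
}


def preset(name: str, seed: int) -> SyntheticConfig:
    """A named scenario: ``null``, ``headline`` (the default), ``stress``."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return SyntheticConfig(seed=seed, **PRESETS[name])
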