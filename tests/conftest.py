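"""Shared fixtures: hand-written quarter files and the headline scenario."""

from __future__ import annotations

from pathlib import Path

import pytest

import faers_signals as fs

DEMO_COLS = ["primaryid", "caseid", "caseversion", "event_dt", "fda_dt",
             "age", "age_cod", "sex", "occr_country", "reporter_country"]
DRUG_COLS = ["primaryid", "drug_seq", "role_cod", "drugname", "prod_ai"]
REAC_COLS = ["primaryid", "pt"]
OUTC_COLS = ["primaryid", "outc_cod"]

_DEFAULTS = {
    "caseversion": "1",
    "event_dt": "20200115",
    "fda_dt": "20200130",
    "age": "60",
    "age_cod": "YR",
    "sex": "F",
    "occr_country": "US",
    "reporter_country": "US",
    "drug_seq": "1",
    "role_cod": "PS",
    "prod_ai": "",
}


def write_table(path: Path, cols: list[str], rows: list[dict]) -> Path:
    lines = ["$".join(cols)]
    for row in rows:
        lines.append("$".join(str(row.get(c, _DEFAULTS.get(c, ""))) for c in cols))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


@pytest.fixture
def make_quarter(tmp_path):
    """Factory writing a quarter's files from row dicts and loading the bundle."""

    def _make(label="2020Q1", demo=(), drug=(), reac=(), outc=(), deleted=None,
              load=True):
        d = tmp_path / label
        d.mkdir(exist_ok=True)
        write_table(d / f"DEMO{label}.txt", DEMO_COLS, list(demo))
        write_table(d / f"DRUG{label}.txt", DRUG_COLS, list(drug))
        write_table(d / f"REAC{label}.txt", REAC_COLS, list(reac))
        write_table(d / f"OUTC{label}.txt", OUTC_COLS, list(outc))
        if deleted is not None:
            write_table(d / f"DELETED{label}.txt", ["primaryid"],
                        [{"primaryid": pid} for pid in deleted])
        if not load:
            return d
        return fs.load_quarter_bundle(d, label)

    return _make


@pytest.fixture(scope="session")
def headline_run():
    """The default synthetic scenario run end to end once per session.

    200 drugs x 100 events, 200,000 expected reports, one pair injected at
    relative risk 10 with a null expectation near 20, seed 1 — then cohort
    construction, hyperparameter fitting and whole-grid signal scoring.
    """
    config = fs.preset("headline", seed=1)
    bundles, truth = fs.generate_database(config)
    cohort, audit = fs.build_cohort(
        bundles, fs.FilterConfig(target_pt="EVENT_001"), fs.default_class_map()
    )
    pairs = fs.pair_grid_from_cohort(cohort)
    est = fs.GammaPoissonShrinkage().fit(pairs["n"].to_numpy(), pairs["e"].to_numpy())
    scores = fs.score_pair_grid(pairs, est.prior_)
    return {
        "config": config,
        "truth": truth,
        "cohort": cohort,
        "audit": audit,
        "pairs": pairs,
        "prior": est.prior_,
        "scores": scores,
    }
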