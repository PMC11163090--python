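"""Deduplication, window filtering, class mapping and cohort assembly."""

import pandas as pd
import pytest

import faers_signals as fs
from faers_signals.cohort import ClassMapError, deduplicate_reports, filter_window


def _basic_rows(reac_pt="Pancreatitis"):
    demo = [
        {"primaryid": "101", "caseid": "1", "caseversion": "1", "event_dt": "20200101"},
        {"primaryid": "102", "caseid": "1", "caseversion": "2", "event_dt": "20200101"},
        {"primaryid": "201", "caseid": "2", "caseversion": "1", "event_dt": "20200501"},
        {"primaryid": "301", "caseid": "3", "caseversion": "1", "event_dt": "20200901"},
    ]
    reac = [{"primaryid": p, "pt": reac_pt} for p in ("101", "102", "201", "301")]
    return demo, reac


class TestDeduplicate:
    def test_latest_caseversion_retained(self, make_quarter):
        demo, reac = _basic_rows()
        bundle = make_quarter(demo=demo, reac=reac)
        kept, audit = deduplicate_reports([bundle])
        assert audit["version_collapsed"] == 1
        assert set(kept["primaryid"]) == {"102", "201", "301"}
        assert len(kept) == 3  # three distinct caseids survive

    def test_identical_case_date_pt_collapses(self, make_quarter):
        demo = [
            {"primaryid": "101", "caseid": "1", "caseversion": "1", "event_dt": "20200101"},
            {"primaryid": "109", "caseid": "1", "caseversion": "1", "event_dt": "20200101"},
        ]
        reac = [{"primaryid": p, "pt": "Pancreatitis"} for p in ("101", "109")]
        bundle = make_quarter(demo=demo, reac=reac)
        kept, audit = deduplicate_reports([bundle])
        assert len(kept) == 1
        assert audit["duplicate_collapsed"] == 1

    def test_idempotent_and_order_invariant(self, make_quarter, tmp_path):
        config = fs.SyntheticConfig(seed=13, n_drugs=8, n_events=5, n_reports=600,
                                    duplicate_rate=0.1, version_rate=0.1)
        bundles, _ = fs.generate_database(config)
        kept_fwd, _ = deduplicate_reports(bundles)
        kept_rev, _ = deduplicate_reports(list(reversed(bundles)))
        pd.testing.assert_frame_equal(kept_fwd, kept_rev)
        again, audit2 = deduplicate_reports(
            [fs.QuarterBundle(demo=kept_fwd.drop(columns="pts"),
                              drug=bundles[0].drug.iloc[:0],
                              reac=pd.concat([b.reac for b in bundles]),
                              outc=bundles[0].outc.iloc[:0])]
        )
        assert len(again) == len(kept_fwd)
        assert audit2["version_collapsed"] == 0
        assert audit2["duplicate_collapsed"] == 0


class TestWindow:
    def test_year_window_selection(self, make_quarter):
        demo = [
            {"primaryid": "1", "caseid": "1", "event_dt": "20181201"},
            {"primaryid": "2", "caseid": "2", "event_dt": "20190101"},
            {"primaryid": "3", "caseid": "3", "event_dt": "20211231"},
            {"primaryid": "4", "caseid": "4", "event_dt": "20220101"},
        ]
        bundle = make_quarter(demo=demo)
        kept, audit = filter_window(bundle.demo, fs.FilterConfig(2019, 2021))
        assert set(kept["primaryid"]) == {"2", "3"}
        assert audit["out_of_window_excluded"] == 2

    def test_missing_both_dates_excluded_and_tallied(self, make_quarter):
        demo = [
            {"primaryid": "1", "caseid": "1", "event_dt": "", "fda_dt": ""},
            {"primaryid": "2", "caseid": "2", "event_dt": "", "fda_dt": "20200601"},
        ]
        bundle = make_quarter(demo=demo)
        kept, audit = filter_window(bundle.demo, fs.FilterConfig(2019, 2021))
        assert audit["missing_year_excluded"] == 1
        assert list(kept["primaryid"]) == ["2"]
        assert kept["year_source"].iloc[0] == "fda_dt"  # fallback date source


class TestClassMapping:
    def test_brand_name_maps_to_class(self):
        cm = fs.default_class_map()
        assert fs.map_drug_classes({"victoza"}, cm) == frozenset({"GLP-1 RA"})

    def test_non_ps_roles_never_contribute(self, make_quarter):
        bundle = make_quarter(
            demo=[{"primaryid": "1", "caseid": "1"}],
            drug=[{"primaryid": "1", "drugname": "sitagliptin", "role_cod": "SS"}],
            reac=[{"primaryid": "1", "pt": "Pancreatitis"}],
        )
        cohort, _ = fs.build_cohort([bundle], fs.FilterConfig(2019, 2021),
                                    fs.default_class_map())
        assert cohort["drug_classes"].iloc[0] == frozenset()

    def test_two_classes_union(self):
        cm = fs.default_class_map()
        classes = fs.map_drug_classes({"liraglutide", "empagliflozin"}, cm)
        assert classes == frozenset({"GLP-1 RA", "SGLT2 inhibitor"})

    def test_empty_map_is_configuration_error(self):
        with pytest.raises(ClassMapError):
            fs.DrugClassMap(pd.DataFrame(columns=["class_name", "drug_name", "is_reference"]))

    def test_drug_in_two_classes_rejected(self):
        df = pd.DataFrame({
            "class_name": ["A", "B"],
            "drug_name": ["metformin", "Metformin"],
            "is_reference": [False, False],
        })
        with pytest.raises(ClassMapError, match="more than one class"):
            fs.DrugClassMap(df)


class TestEventFlag:
    @pytest.mark.parametrize("pts,expected", [
        (("Pancreatitis", "Nausea"), True),
        (("Pancreatitis acute",), False),  # exact match only, no substrings
        ((), False),
        (("  PANCREATITIS ",), True),
    ])
    def test_exact_normalized_match(self, pts, expected):
        assert fs.flag_event(pts, "pancreatitis") is expected

    def test_term_list_mode(self):
        assert fs.flag_event(("Pancreatitis acute",), "pancreatitis",
                             extra_terms=["pancreatitis acute"]) is True


class TestBuildCohort:
    def test_audit_matches_generator_ground_truth(self):
        config = fs.SyntheticConfig(
            seed=23, n_drugs=10, n_events=6, n_reports=500,
            duplicate_rate=0.04, version_rate=0.03,
            year_range=(2018, 2022), missing_both_dates_rate=0.02,
        )
        bundles, truth = fs.generate_database(config)
        cohort, audit = fs.build_cohort(bundles, fs.FilterConfig(2019, 2021),
                                        fs.default_class_map())
        assert audit["version_collapsed"] == truth.n_versions
        assert audit["duplicate_collapsed"] == truth.n_duplicates
        assert audit["out_of_window_excluded"] == truth.out_of_window_cases
        assert audit["missing_year_excluded"] == truth.missing_year_cases
        assert len(cohort) == truth.in_window_cases
        assert cohort["caseid"].is_unique

    def test_audit_conservation(self):
        config = fs.SyntheticConfig(seed=29, n_drugs=10, n_events=6, n_reports=800,
                                    duplicate_rate=0.05, version_rate=0.05,
                                    year_range=(2018, 2022))
        bundles, _ = fs.generate_database(config)
        _, audit = fs.build_cohort(bundles, fs.FilterConfig(2019, 2021),
                                   fs.default_class_map())
        assert audit["input_reports"] == (
            audit["final_cohort"]
            + audit["version_collapsed"]
            + audit["duplicate_collapsed"]
            + audit["missing_year_excluded"]
            + audit["out_of_window_excluded"]
        )

    def test_empty_bundle_gives_empty_cohort(self, make_quarter):
        bundle = make_quarter(demo=[], drug=[], reac=[], outc=[])
        cohort, audit = fs.build_cohort([bundle], fs.FilterConfig(2019, 2021),
                                        fs.default_class_map())
        assert cohort.empty
        assert audit["final_cohort"] == 0
        assert audit["input_reports"] == 0
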