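"""Input validation: check suite order, row addressing, normalization, round-trips."""

import pandas as pd
import pytest

from aquaqc import (
    ChecksFailedError,
    BundleError,
    bundle,
    corrupt_bundle,
    read_accuracy,
    read_frecom,
    read_results,
    read_sites,
    read_wqx,
    results_view,
)
from aquaqc.tabular_io import load_table, normalize_date, write_table

EXPECTED_CHECKS = [
    "Checking column names",
    "Checking all required columns are present",
    "Checking valid Activity Types",
    "Checking Activity Start Date formats",
    "Checking depth data present",
    "Checking for non-numeric values in Activity Depth/Height Measure",
    "Checking Activity Depth/Height Unit",
    "Checking Activity Relative Depth Name formats",
    "Checking values in Activity Depth/Height Measure > 1 m / 3.3 ft",
    "Checking Characteristic Name formats",
    "Checking Result Values",
    "Checking QC Reference Values",
    "Checking for missing entries for Result Unit",
    "Checking if more than one unit per Characteristic Name",
    "Checking acceptable units for each entry in Characteristic Name",
]


class TestResultsChecks:
    def test_valid_bundle_passes_all_fifteen_checks_in_order(self, default_bundle):
        b, _ = default_bundle
        _, outcomes = read_results(b.results)
        assert [o.check_name for o in outcomes] == EXPECTED_CHECKS
        assert all(o.status == "ok" for o in outcomes)

    def test_corrupted_activity_types_abort_with_values_and_rows(self, default_bundle):
        b, _ = default_bundle
        chk, _ = corrupt_bundle(
            b.results,
            [(4, "Activity Type", "Sample"), (135, "Activity Type", "Field")],
        )
        with pytest.raises(ChecksFailedError) as exc:
            read_results(chk)
        outcomes = exc.value.outcomes
        failed = outcomes[-1]
        assert failed.check_name == "Checking valid Activity Types"
        assert failed.offending_values == ["Sample", "Field"]
        assert failed.offending_rows == [4, 135]
        assert "Incorrect Activity Type found: Sample, Field in row(s) 4, 135" in failed.message

    def test_abort_on_first_failure_runs_no_later_checks(self, default_bundle):
        b, _ = default_bundle
        chk, _ = corrupt_bundle(b.results, [(4, "Activity Type", "Sample")])
        with pytest.raises(ChecksFailedError) as exc:
            read_results(chk)
        outcomes = exc.value.outcomes
        assert sum(o.status == "fail" for o in outcomes) == 1
        assert outcomes[-1].status == "fail"
        assert len(outcomes) == 3  # two passed checks, then the failure

    def test_missing_column_fails_at_check_two(self, default_bundle):
        b, _ = default_bundle
        chk, _ = corrupt_bundle(b.results, [("drop_column", "Result Unit")])
        with pytest.raises(ChecksFailedError) as exc:
            read_results(chk)
        failed = exc.value.outcomes[-1]
        assert failed.check_name == "Checking all required columns are present"
        assert "Result Unit" in failed.message

    def test_deep_sample_warns_but_does_not_abort(self, default_bundle):
        b, _ = default_bundle
        chk, _ = corrupt_bundle(b.results, [(10, "Activity Depth/Height Measure", "2.5")])
        _, outcomes = read_results(chk)
        depth = outcomes[8]
        assert depth.check_name == EXPECTED_CHECKS[8]
        assert depth.status == "warn"
        assert depth.offending_rows == [10]

    def test_strict_mode_promotes_warnings_to_failures(self, default_bundle):
        b, _ = default_bundle
        chk, _ = corrupt_bundle(b.results, [(10, "Activity Depth/Height Measure", "2.5")])
        with pytest.raises(ChecksFailedError):
            read_results(chk, strict=True)

    def test_missing_time_warns(self, default_bundle):
        b, _ = default_bundle
        chk, _ = corrupt_bundle(b.results, [(7, "Activity Start Time", "")])
        _, outcomes = read_results(chk)
        date_check = outcomes[3]
        assert date_check.status == "warn"
        assert date_check.offending_rows == [7]

    def test_wrong_unit_for_parameter_fails_last_check(self, default_bundle):
        b, _ = default_bundle
        # change every DO row so the one-unit-per-parameter check still passes
        do_rows = [
            i + 1
            for i, (p, at) in enumerate(
                zip(b.results["Characteristic Name"], b.results["Activity Type"])
            )
            if p == "DO"
        ]
        chk, _ = corrupt_bundle(
            b.results, [(r, "Result Unit", "NTU") for r in do_rows]
        )
        with pytest.raises(ChecksFailedError) as exc:
            read_results(chk)
        assert exc.value.outcomes[-1].check_name == EXPECTED_CHECKS[14]

    def test_inconsistent_unit_fails_one_unit_check(self, default_bundle):
        b, _ = default_bundle
        tp_row = next(
            i + 1
            for i, p in enumerate(b.results["Characteristic Name"])
            if p == "TP"
        )
        chk, _ = corrupt_bundle(b.results, [(tp_row, "Result Unit", "ug/l")])
        with pytest.raises(ChecksFailedError) as exc:
            read_results(chk)
        assert exc.value.outcomes[-1].check_name == EXPECTED_CHECKS[13]


class TestDateNormalization:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ("2022-05-15", "2022-05-15"),
            ("5/15/2022", "2022-05-15"),
            ("2022-05-15 00:00:00", "2022-05-15"),
            ("44696", "2022-05-15"),  # spreadsheet serial day
        ],
    )
    def test_accepted_forms(self, raw, expected):
        assert normalize_date(raw) == expected

    def test_idempotent_on_results(self, default_bundle):
        b, _ = default_bundle
        again, _ = read_results(b.results)
        pd.testing.assert_frame_equal(again, b.results)


class TestRoundTrip:
    @pytest.mark.parametrize("ext", ["csv", "xlsx"])
    def test_write_read_round_trips_all_cells(self, default_bundle, tmp_path, ext):
        b, _ = default_bundle
        path = write_table(b.results, tmp_path / f"results.{ext}")
        back = load_table(path)
        pd.testing.assert_frame_equal(back, b.results)
        assert (back["Result Value"] == "BDL").sum() == (
            b.results["Result Value"] == "BDL"
        ).sum()


class TestResultsView:
    def test_uniques_match_brute_force_in_first_appearance_order(self, default_bundle):
        b, _ = default_bundle
        view = results_view(b.results)
        for col in b.results.columns:
            brute = list(dict.fromkeys(v for v in b.results[col] if v != ""))
            got = [v for v in view[col] if v != ""]
            assert got == brute

    def test_empty_column_gives_empty_unique_list(self):
        df = pd.DataFrame({"a": ["x", "y", "x"], "b": ["", "", ""]})
        view = results_view(df)
        assert list(view["a"]) == ["x", "y"]
        assert all(v == "" for v in view["b"])


class TestDqoFiles:
    def test_unknown_parameter_rejected(self, default_bundle):
        b, _ = default_bundle
        acc = b.accuracy.copy()
        acc.loc[0, "Parameter"] = "Unobtainium"
        with pytest.raises(ValueError, match="Unobtainium"):
            read_accuracy(acc)

    def test_malformed_criterion_names_cell(self, default_bundle):
        b, _ = default_bundle
        acc = b.accuracy.copy()
        acc.loc[1, "Field Blank"] = "approximately small"
        with pytest.raises(ValueError, match="row 2.*Field Blank"):
            read_accuracy(acc)

    def test_log_token_sets_scale_hint(self, default_bundle):
        b, _ = default_bundle
        rules = b.rules
        assert all(r.scale_hint == "log" for r in rules["E.coli"])
        assert all(r.scale_hint == "linear" for r in rules["DO"])

    def test_frecom_out_of_range_percent_names_cell(self, default_bundle):
        b, _ = default_bundle
        fre = b.frecom.copy()
        fre.loc[0, "Field Duplicate"] = "120"
        with pytest.raises(ValueError, match="row 1.*Field Duplicate"):
            read_frecom(fre)

    def test_empty_cells_mean_no_requirement(self, default_bundle):
        b, _ = default_bundle
        fre = b.frecom.copy()
        fre.loc[:, "Lab Duplicate"] = ""
        assert read_frecom(fre) is not None


class TestSitesAndWqx:
    def test_out_of_bounds_latitude_rejected(self, default_bundle):
        b, _ = default_bundle
        sites = b.sites.copy()
        sites.loc[0, "Monitoring Location Latitude"] = "100"
        with pytest.raises(ValueError, match="Latitude"):
            read_sites(sites)

    def test_duplicate_site_id_rejected(self, default_bundle):
        b, _ = default_bundle
        sites = pd.concat([b.sites, b.sites.iloc[[0]]], ignore_index=True)
        with pytest.raises(ValueError, match=sites.iloc[0]["Monitoring Location ID"]):
            read_sites(sites)

    def test_wqx_unknown_parameter_rejected(self, default_bundle):
        b, _ = default_bundle
        wqx = b.wqx.copy()
        wqx.loc[0, "Parameter"] = "Kryptonite"
        with pytest.raises(ValueError, match="Kryptonite"):
            read_wqx(wqx)


class TestBundle:
    def test_bundle_without_sites_accepted_for_qc_reporting(self, default_bundle):
        b, _ = default_bundle
        partial = bundle(b.results, b.accuracy, frecom=b.frecom)
        partial.require("qc_reporting")  # must not raise

    def test_bundle_without_wqx_rejected_for_wqx_step(self, default_bundle):
        b, _ = default_bundle
        partial = bundle(b.results, b.accuracy, frecom=b.frecom, sites=b.sites)
        with pytest.raises(BundleError, match="WQX metadata"):
            partial.require("wqx_formatting")

    def test_full_bundle_accepted_everywhere(self, default_bundle):
        b, _ = default_bundle
        for step in ("qc_screening", "qc_reporting", "analysis", "wqx_formatting"):
            b.require(step)
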