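"""QC evaluation: acceptance arithmetic, evaluators, table coherence, report."""

from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aquaqc import (
    bundle,
    eval_blank,
    eval_completeness,
    eval_duplicate,
    eval_frequency,
    eval_spike,
    percent_acceptance,
    qc_individual,
    tab_accuracy,
    assemble_report,
)
from aquaqc.criteria import parse_criterion
from aquaqc.tabular_io import AccuracyRule


def make_rule(parameter="TP", mdl=0.01, uql=1.0, **criteria):
    defaults = {
        "Field Duplicate": None,
        "Lab Duplicate": None,
        "Field Blank": None,
        "Lab Blank": None,
        "Spike/Check Accuracy": None,
    }
    defaults.update(
        {k: parse_criterion(v) if isinstance(v, str) else v for k, v in criteria.items()}
    )
    return AccuracyRule(
        parameter=parameter,
        mdl=mdl,
        uql=uql,
        value_range=None,
        criteria=defaults,
        scale_hint="linear",
        order=0,
    )


class TestPercentAcceptance:
    @pytest.mark.parametrize(
        "n, m, expected",
        [
            (4, 1, 75),  # three of four field duplicates accepted
            (7, 1, 86),  # 85.714 rounds to 86
            (11, 1, 91),  # 90.909 rounds to 91
            (7, 0, 100),
            (0, 0, "-"),  # no QC records available
        ],
    )
    def test_printed_percentages(self, n, m, expected):
        assert percent_acceptance(n, m) == expected

    def test_agrees_with_exact_rational_rounding_for_all_n_up_to_50(self):
        """Oracle: exact rational arithmetic, half rounded away from zero."""
        for n in range(1, 51):
            for m in range(0, n + 1):
                x = Fraction(100 * (n - m), n)
                expected = int(x) + (1 if x - int(x) >= Fraction(1, 2) else 0)
                assert percent_acceptance(n, m) == expected, (n, m)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            percent_acceptance(-1, 0)
        with pytest.raises(ValueError):
            percent_acceptance(2, 3)

    @given(n=st.integers(1, 200), m=st.integers(0, 200))
    @settings(max_examples=200, deadline=None)
    def test_monotonicity(self, n, m):
        """Adding a miss never increases acceptance; adding a hit never lowers it."""
        m = min(m, n)
        base = percent_acceptance(n, m)
        assert percent_acceptance(n + 1, m) >= base
        if m < n:
            assert percent_acceptance(n + 1, m + 1) <= base


class TestBlankEvaluation:
    def test_censored_blank_is_hit(self):
        rule = make_rule(**{"Field Blank": "< 0.01"})
        r = eval_blank("BDL", rule, "field", unit="mg/l")
        assert r.verdict == "hit"
        assert r.result_display == "BDL"
        assert r.threshold_display == "0.01 mg/l"

    def test_value_equal_to_strict_threshold_is_miss(self):
        rule = make_rule(**{"Field Blank": "< 0.01"})
        assert eval_blank("0.01", rule, "field").verdict == "miss"

    def test_value_strictly_below_threshold_is_hit(self):
        rule = make_rule(**{"Field Blank": "< 0.01"})
        assert eval_blank("0.005", rule, "field").verdict == "hit"

    def test_missing_criterion_excludes_record(self):
        rule = make_rule()
        assert eval_blank("BDL", rule, "field") is None


class TestDuplicateEvaluation:
    def test_rpd_within_percent_criterion_is_hit(self):
        # RPD of (10, 12) = 100 * 2 / 11 = 18.18...%
        rule = make_rule(**{"Field Duplicate": "<= 30%"})
        assert eval_duplicate("10", "12", rule, "field").verdict == "hit"

    def test_rpd_beyond_percent_criterion_is_miss(self):
        rule = make_rule(**{"Field Duplicate": "<= 30%"})
        # RPD of (10, 14) = 400/12 = 33.3%
        assert eval_duplicate("10", "14", rule, "field").verdict == "miss"

    def test_identical_pair_is_hit(self):
        rule = make_rule(**{"Field Duplicate": "<= 30%"})
        assert eval_duplicate("5", "5", rule, "field").verdict == "hit"

    def test_both_censored_is_hit(self):
        rule = make_rule(**{"Lab Duplicate": "<= 20%"})
        assert eval_duplicate("BDL", "BDL", rule, "lab").verdict == "hit"

    def test_mixed_pair_substitutes_half_mdl(self):
        # BDL -> 0.005; RPD with 0.006 = 100*0.001/0.0055 = 18.2% -> hit
        rule = make_rule(mdl=0.01, **{"Lab Duplicate": "<= 20%"})
        assert eval_duplicate("BDL", "0.006", rule, "lab").verdict == "hit"
        # RPD with 0.05 = 100*0.045/0.0275 = 164% -> miss
        assert eval_duplicate("BDL", "0.05", rule, "lab").verdict == "miss"

    def test_zero_mean_falls_back_to_equality(self):
        rule = make_rule(parameter="Water Temp", **{"Field Duplicate": "<= 10%"})
        assert eval_duplicate("0", "0", rule, "field").verdict == "hit"
        assert eval_duplicate("-1", "1", rule, "field").verdict == "miss"

    def test_absolute_criterion_compares_difference(self):
        rule = make_rule(parameter="pH", **{"Field Duplicate": "<= 0.5"})
        assert eval_duplicate("7.0", "7.4", rule, "field").verdict == "hit"
        assert eval_duplicate("7.0", "7.6", rule, "field").verdict == "miss"


class TestSpikeEvaluation:
    def test_two_percent_recovery_error_is_hit(self):
        rule = make_rule(**{"Spike/Check Accuracy": "<= 5%"})
        assert eval_spike("98", "100", rule).verdict == "hit"

    def test_measured_equals_known_is_hit(self):
        rule = make_rule(**{"Spike/Check Accuracy": "<= 5%"})
        assert eval_spike("100", "100", rule).verdict == "hit"

    def test_ten_percent_error_misses_five_percent_criterion(self):
        rule = make_rule(**{"Spike/Check Accuracy": "<= 5%"})
        assert eval_spike("90", "100", rule).verdict == "miss"

    def test_zero_known_quantity_excluded(self):
        rule = make_rule(**{"Spike/Check Accuracy": "<= 5%"})
        assert eval_spike("1", "0", rule) is None


class TestBlankWorkedExample:
    """The 18 field-blank records: 7 ammonia (all BDL), 11 TP with one miss."""

    def test_summary_counts(self, blank_bundle):
        s = tab_accuracy(blank_bundle, "summary")
        s = s.set_index("Parameter")
        assert s.loc["Ammonia", "Number of QC Checks"] == 7
        assert s.loc["Ammonia", "Number of Misses"] == 0
        assert s.loc["Ammonia", "% Acceptance"] == "100%"
        assert s.loc["TP", "Number of QC Checks"] == 11
        assert s.loc["TP", "Number of Misses"] == 1
        assert s.loc["TP", "% Acceptance"] == "91%"

    def test_individual_hit_miss_column(self, blank_bundle):
        ind = tab_accuracy(blank_bundle, "individual", accchk=["Field Blanks"])
        misses = ind[ind["Hit/Miss"] == "MISS"]
        assert len(misses) == 1
        row = misses.iloc[0]
        assert row["Parameter"] == "TP"
        assert row["Date"] == "2022-07-17"
        assert row["Result"] == "0.01 mg/l"
        assert row["Threshold"] == "0.01 mg/l"

    def test_percent_view(self, blank_bundle):
        pct = tab_accuracy(blank_bundle, "percent").set_index("Parameter")
        assert pct.loc["Ammonia", "Field Blanks"] == "100%"
        assert pct.loc["TP", "Field Blanks"] == "91%"
        # no lab records in this fixture: no-data marker
        assert pct.loc["Ammonia", "Lab Duplicates"] == "-"


class TestTableCoherence:
    @pytest.mark.parametrize("seed", [7, 21])
    def test_summary_equals_tally_of_individual_and_percent_matrix(self, seed):
        """Individual verdicts, summary counts, and the percent matrix agree."""
        from aquaqc import FixtureSpec, generate_bundle

        b, _ = generate_bundle(FixtureSpec(seed=seed))
        individual = qc_individual(b)
        summary = tab_accuracy(b, "summary")
        percent = tab_accuracy(b, "percent").set_index("Parameter")
        tallies = {}
        for r in individual:
            key = (r.check_type, r.parameter)
            n, m = tallies.get(key, (0, 0))
            tallies[key] = (n + 1, m + (r.verdict == "miss"))
        assert len(summary) == len(tallies)
        for _, row in summary.iterrows():
            n, m = tallies[(row["Type"], row["Parameter"])]
            assert row["Number of QC Checks"] == n
            assert row["Number of Misses"] == m
            expected_pct = percent_acceptance(n, m)
            shown = f"{expected_pct}%" if expected_pct != "-" else "-"
            assert row["% Acceptance"] == shown
            assert percent.loc[row["Parameter"], row["Type"]] == shown

    def test_miss_counts_match_injected_ground_truth(self, default_bundle):
        b, sidecar = default_bundle
        summary = tab_accuracy(b, "summary")
        observed = {}
        for _, row in summary.iterrows():
            if row["Number of Misses"]:
                observed.setdefault(row["Parameter"], {})[row["Type"]] = int(
                    row["Number of Misses"]
                )
        assert observed == sidecar["qc_misses"]


class TestFrequencyCompleteness:
    def test_frequency_matches_sidecar_counts(self, default_bundle):
        b, sidecar = default_bundle
        freq = eval_frequency(b)
        for _, row in freq.iterrows():
            p, ct = row["Parameter"], row["Check"]
            n_reg = sidecar["regular_counts"][p] - sidecar["qualified_counts"][p]
            assert row["Number of Regular Samples"] == n_reg
            assert row["Number of QC Checks"] == sidecar["qc_counts"][p][ct]
            expected = 100.0 * row["Number of QC Checks"] / n_reg
            assert row["Frequency %"] == pytest.approx(expected, abs=0.05)
            assert bool(row["Met"]) == (expected >= row["Required %"])

    def test_completeness_matches_sidecar_counts(self, default_bundle):
        b, sidecar = default_bundle
        comp = eval_completeness(b).set_index("Parameter")
        for p, row in comp.iterrows():
            n = sidecar["regular_counts"][p]
            q = sidecar["qualified_counts"][p]
            assert row["Number of Records"] == n
            assert row["Number of Qualified"] == q
            assert row["% Completeness"] == pytest.approx(100 * (n - q) / n, abs=0.05)

    def test_zero_qc_checks_reported_not_met(self, blank_bundle):
        freq = eval_frequency(blank_bundle)
        # the canned blank fixture has no regular samples at all
        assert (freq["Frequency %"] == "-").all()


class TestReport:
    def test_report_contains_all_sections_and_success_message(
        self, default_bundle, tmp_path, capsys
    ):
        b, _ = default_bundle
        path = assemble_report(b, tmp_path)
        text = path.read_text()
        for heading in (
            "Data Quality Objectives: Accuracy",
            "Data Quality Objectives: Frequency and Completeness",
            "QC Frequency Results",
            "QC Completeness Results",
            "Accuracy Summary",
            "Accuracy Percent Acceptance",
            "Individual Results: Field Duplicates",
            "Individual Results: Lab Spikes / Instrument Checks",
        ):
            assert heading in text
        out = capsys.readouterr().out
        assert "Report created successfully! File located at" in out
        assert str(path) in out

    def test_report_is_deterministic(self, default_bundle, tmp_path):
        b, _ = default_bundle
        p1 = assemble_report(b, tmp_path / "a")
        p2 = assemble_report(b, tmp_path / "b")
        assert p1.read_bytes() == p2.read_bytes()

    def test_empty_accuracy_criteria_produce_report_without_crash(
        self, default_bundle, tmp_path
    ):
        b, _ = default_bundle
        acc = b.accuracy.copy()
        for col in ("Field Duplicate", "Lab Duplicate", "Field Blank",
                    "Lab Blank", "Spike/Check Accuracy"):
            acc[col] = ""
        empty = bundle(b.results, acc, frecom=b.frecom)
        path = assemble_report(empty, tmp_path)
        assert "Accuracy Summary" in path.read_text()

    def test_html_report_marks_misses(self, default_bundle, tmp_path):
        b, _ = default_bundle
        path = assemble_report(b, tmp_path, format="html")
        assert 'class="miss"' in path.read_text() or "MISS" in path.read_text()
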