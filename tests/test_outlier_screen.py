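"""Outlier screening: oracle agreement, invariances, censored substitution."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aquaqc import FixtureSpec, detect_outliers, generate_bundle, iqr_bounds
from aquaqc.outlier_screen import substitute_censored
from aquaqc.tabular_io import AccuracyRule


def brute_force_flags(values, k=1.5):
    """Independent oracle: quartiles by linear interpolation, flag strictly outside."""
    arr = np.sort(np.asarray(values, dtype=float))
    n = len(arr)

    def quantile(q):
        h = (n - 1) * q
        lo = int(np.floor(h))
        hi = min(lo + 1, n - 1)
        return arr[lo] + (h - lo) * (arr[hi] - arr[lo])

    q1, q3 = quantile(0.25), quantile(0.75)
    iqr = q3 - q1
    return {x for x in values if x < q1 - k * iqr or x > q3 + k * iqr}


def rule(mdl=0.1, uql=10.0):
    return AccuracyRule(
        parameter="TP", mdl=mdl, uql=uql, value_range=None,
        criteria={}, scale_hint="linear", order=0,
    )


class TestIqrBounds:
    def test_simple_group_flags_only_extreme(self):
        lo, hi = iqr_bounds([1, 2, 3, 4, 100])
        flagged = {x for x in [1, 2, 3, 4, 100] if x < lo or x > hi}
        assert flagged == brute_force_flags([1, 2, 3, 4, 100]) == {100}

    def test_identical_values_produce_no_flags(self):
        lo, hi = iqr_bounds([5.0] * 8)
        assert lo == hi == 5.0

    def test_thousand_random_groups_match_brute_force(self):
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            n = int(rng.integers(4, 40))
            values = np.round(rng.normal(10, 3, n), 3)
            if rng.random() < 0.3:  # sprinkle genuine extremes
                values[0] = values[0] + rng.choice([-1, 1]) * 50
            lo, hi = iqr_bounds(values)
            flagged = {x for x in values if x < lo or x > hi}
            assert flagged == brute_force_flags(values)

    @given(
        st.lists(st.floats(min_value=0.1, max_value=1e4, allow_nan=False),
                 min_size=4, max_size=30)
    )
    @settings(max_examples=200, deadline=None)
    def test_log_flags_equal_raw_flags_under_log_transform(self, values):
        """Monotone-transform invariance: flagging log10 values against
        log-space bounds marks the same observations as flagging raw values
        against the back-transformed bounds."""
        raw = np.asarray(values)
        logs = np.log10(raw)
        lo, hi = iqr_bounds(logs)
        flags_log = {i for i, v in enumerate(logs) if v < lo or v > hi}
        # back-transform with a float-noise guard band: only the comparison's
        # monotonicity is under test, not 10**log10 round-trip exactness
        raw_lo, raw_hi = 10**lo * (1 - 1e-12), 10**hi * (1 + 1e-12)
        flags_raw = {i for i, v in enumerate(raw) if v < raw_lo or v > raw_hi}
        assert flags_log == flags_raw

    @given(
        st.lists(st.floats(min_value=-100, max_value=100, allow_nan=False),
                 min_size=5, max_size=25)
    )
    @settings(max_examples=200, deadline=None)
    def test_duplicating_the_median_never_removes_flags(self, values):
        """Inserting the median tightens the quartile interval, so points
        already flagged stay flagged (the converse — that no new borderline
        flags appear — does not hold for interpolated quartiles)."""
        base_lo, base_hi = iqr_bounds(values)
        flagged_before = {x for x in values if x < base_lo or x > base_hi}
        med = float(np.median(values))
        lo, hi = iqr_bounds(values + [med])
        flagged_after = {x for x in values + [med] if x < lo or x > hi}
        assert flagged_before <= flagged_after


class TestSubstitution:
    def test_bdl_becomes_half_mdl(self):
        vals, kept = substitute_censored(["BDL"], rule(mdl=0.1))
        assert vals == [0.05] and kept == [0]

    def test_aql_becomes_uql(self):
        vals, kept = substitute_censored(["AQL"], rule(uql=10))
        assert vals == [10.0]

    def test_numeric_passes_through(self):
        vals, _ = substitute_censored(["0.3", 0.4], rule())
        assert vals == [0.3, 0.4]

    def test_token_without_limit_excluded(self):
        vals, kept = substitute_censored(["BDL", "1.0"], rule(mdl=None))
        assert vals == [1.0] and kept == [1]


class TestDetectOutliers:
    def test_injected_outliers_recovered_exactly(self, default_bundle):
        b, sidecar = default_bundle
        hits = detect_outliers(b, "DO", group="month")
        got = set(
            zip(hits["Monitoring Location ID"], hits["Activity Start Date"],
                hits["Result Value"])
        )
        want = {
            (o["Monitoring Location ID"], o["Activity Start Date"], o["Result Value"])
            for o in sidecar["outliers"]
        }
        assert got == want

    @pytest.mark.parametrize("seed", [3, 11, 99])
    def test_recovery_holds_across_seeds(self, seed):
        b, sidecar = generate_bundle(FixtureSpec(seed=seed))
        hits = detect_outliers(b, "DO", group="month")
        got = set(zip(hits["Monitoring Location ID"], hits["Activity Start Date"]))
        want = {
            (o["Monitoring Location ID"], o["Activity Start Date"])
            for o in sidecar["outliers"]
        }
        assert got == want

    def test_output_has_the_six_columns_in_order(self, default_bundle):
        b, _ = default_bundle
        hits = detect_outliers(b, "DO")
        assert list(hits.columns) == [
            "Monitoring Location ID",
            "Activity Start Date",
            "Activity Start Time",
            "Characteristic Name",
            "Result Value",
            "Result Unit",
        ]

    def test_unknown_parameter_raises(self, default_bundle):
        b, _ = default_bundle
        with pytest.raises(ValueError, match="Chl a"):
            detect_outliers(b, "Chl a")

    def test_log_parameter_flags_match_log_scale_oracle(self, default_bundle):
        """Log-hinted parameters are screened on log10 of the substituted
        values; the flag set must equal a brute-force log-space oracle."""
        b, _ = default_bundle
        hits = detect_outliers(b, "E.coli", group="month")
        res = b.results
        sub = res[
            (res["Characteristic Name"] == "E.coli")
            & (res["Activity Type"].isin({"Field Msr/Obs", "Sample-Routine"}))
        ].copy()
        mdl = b.rules["E.coli"][0].mdl
        sub["_v"] = [mdl / 2 if v == "BDL" else float(v) for v in sub["Result Value"]]
        months = pd.to_datetime(sub["Activity Start Date"]).dt.month
        expected = set()
        for _, grp in sub.groupby(months):
            if len(grp) < 4:
                continue
            logs = np.log10(grp["_v"].to_numpy())
            flagged = brute_force_flags(list(logs))
            for (_, row), lv in zip(grp.iterrows(), logs):
                if lv in flagged:
                    expected.add(
                        (row["Monitoring Location ID"], row["Activity Start Date"])
                    )
        got = set(zip(hits["Monitoring Location ID"], hits["Activity Start Date"]))
        assert got == expected


class TestBatch:
    def test_images_format_writes_one_file_per_parameter(self, default_bundle, tmp_path):
        from aquaqc import batch_outliers

        b, _ = default_bundle
        paths = batch_outliers(b, format="images", output_dir=tmp_path)
        n_params = b.results["Characteristic Name"].nunique()
        assert len(paths) == n_params
        assert all(p.exists() for p in paths)

    def test_doc_format_writes_single_document(self, default_bundle, tmp_path):
        from aquaqc import batch_outliers

        b, _ = default_bundle
        paths = batch_outliers(b, format="doc", output_dir=tmp_path)
        assert len(paths) == 1
        text = paths[0].read_text()
        for p in sorted(b.results["Characteristic Name"].unique()):
            assert f"<h2>{p}</h2>" in text

    def test_empty_results_raise(self, default_bundle, tmp_path):
        from aquaqc import batch_outliers, bundle

        b, _ = default_bundle
        empty = bundle(b.results.iloc[0:0], b.accuracy)
        with pytest.raises(ValueError, match="empty"):
            batch_outliers(empty, output_dir=tmp_path)
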