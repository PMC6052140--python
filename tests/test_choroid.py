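"""Tests for the choroidal-thickness statistics pipeline and cohort generator."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from onoffscan import (
    SynthCohortSpec,
    change_from_baseline,
    condition_effect,
    paired_t_test,
    regress_thinning_on_refraction,
    rm_anova,
    simulate_cohort,
    stats_report,
)
from onoffscan.choroid import (
    DegenerateSampleError,
    load_measurements,
    save_measurements,
)

from conftest import anova_f_oracle


def make_table(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "subject", "eye", "condition", "timepoint_min",
            "thickness_um", "spherical_equivalent_d",
        ],
    )


class TestChangeFromBaseline:
    def test_repeats_averaged_before_differencing(self):
        table = make_table(
            [("s1", "right", "dark_text", 0, 250.0, -2.0),
             ("s1", "right", "dark_text", 0, 252.0, -2.0),
             ("s1", "right", "dark_text", 60, 240.0, -2.0),
             ("s1", "right", "dark_text", 60, 238.0, -2.0)]
        )
        changes = change_from_baseline(table)
        assert len(changes) == 1
        assert changes.iloc[0]["change_um"] == pytest.approx(-12.0)

    def test_flat_series_gives_zero_changes(self):
        rows = [("s1", eye, "blank_screen", t, 260.0, 0.0)
                for eye in ("right", "left") for t in (0, 30, 60)]
        changes = change_from_baseline(make_table(rows))
        assert (changes["change_um"] == 0).all()
        assert set(changes["timepoint_min"]) == {30, 60}

    def test_missing_baseline_names_series(self):
        table = make_table(
            [("s1", "right", "dark_text", 0, 250.0, -2.0),
             ("s1", "right", "dark_text", 60, 240.0, -2.0),
             ("s1", "left", "dark_text", 60, 240.0, -2.0)]
        )
        with pytest.raises(ValueError, match="left.*no t=0|no t=0"):
            change_from_baseline(table)

    def test_pooled_estimate_is_average_of_per_eye_estimates(self):
        table = simulate_cohort(SynthCohortSpec(), seed=11)
        changes = change_from_baseline(table)
        pooled = condition_effect(changes, "dark_text").mean
        per_eye = [
            changes[
                (changes["condition"] == "dark_text")
                & (changes["timepoint_min"] == 60)
                & (changes["eye"] == eye)
            ]["change_um"].mean()
            for eye in ("right", "left")
        ]
        assert pooled == pytest.approx(np.mean(per_eye), abs=1e-12)


class TestPairedT:
    def test_symmetric_differences(self):
        res = paired_t_test([-1.0, 1.0])
        assert res.t == 0.0 and res.p == pytest.approx(1.0)

    def test_hand_computed_example(self):
        res = paired_t_test([1.0, 2.0, 3.0, 4.0, 5.0])
        assert res.t == pytest.approx(4.242640687, abs=1e-8)
        assert res.p == pytest.approx(0.013235600, abs=1e-8)
        assert res.mean == 3.0 and res.n == 5

    def test_zero_variance_is_degenerate_not_significant(self):
        with pytest.raises(DegenerateSampleError):
            paired_t_test([2.5, 2.5, 2.5])

    def test_too_few_differences(self):
        with pytest.raises(ValueError):
            paired_t_test([1.0])

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(st.floats(-50, 50), min_size=3, max_size=12).filter(
            lambda d: np.std(d, ddof=1) > 1e-6
        )
    )
    def test_matches_naive_formula(self, diffs):
        """t = mean / (SD / sqrt(n)), p from the t CDF, to 1e-10."""
        res = paired_t_test(diffs)
        d = np.asarray(diffs)
        t = d.mean() / (d.std(ddof=1) / np.sqrt(d.size))
        assert res.t == pytest.approx(t, abs=1e-10)
        assert res.p == pytest.approx(2 * sps.t.sf(abs(t), d.size - 1), abs=1e-10)


class TestRmAnova:
    def hand_table(self):
        # 4 subject-eyes x 3 timepoints with repeats
        values = {
            ("s1", "right"): (250.0, 246.0, 240.0),
            ("s1", "left"): (260.0, 255.0, 247.0),
            ("s2", "right"): (240.0, 239.0, 230.0),
            ("s2", "left"): (270.0, 262.0, 255.0),
        }
        rows = []
        for (subj, eye), series in values.items():
            for t, base in zip((0, 30, 60), series):
                for jitter in (-1.0, 1.0):  # repeats averaging must not bias
                    rows.append((subj, eye, "dark_text", t, base + jitter, -3.0))
        return make_table(rows), np.array(list(values.values()))

    def test_matches_sums_of_squares_oracle(self):
        table, wide = self.hand_table()
        res = rm_anova(table)
        f, df1, df2 = anova_f_oracle(wide)
        assert res.F == pytest.approx(f, abs=1e-10)
        assert (res.df_num, res.df_den) == (df1, df2)
        assert res.p == pytest.approx(sps.f.sf(f, df1, df2), abs=1e-10)

    def test_followup_t_tests_against_baseline(self):
        table, wide = self.hand_table()
        res = rm_anova(table)
        for i, t in enumerate((30, 60)):
            expect = paired_t_test(wide[:, i + 1] - wide[:, 0])
            assert res.followup[t].t == pytest.approx(expect.t, abs=1e-10)

    def test_flat_series_are_degenerate(self):
        rows = [(s, e, "blank_screen", t, 250.0, 0.0)
                for s in ("s1", "s2") for e in ("right", "left") for t in (0, 30, 60)]
        with pytest.raises(DegenerateSampleError):
            rm_anova(make_table(rows))

    def test_incomplete_series_dropped_with_warning(self):
        table, _ = self.hand_table()
        table = table[~((table["subject"] == "s2") & (table["eye"] == "left")
                        & (table["timepoint_min"] == 30))]
        with pytest.warns(UserWarning, match="s2/left"):
            res = rm_anova(table)
        assert res.n_units == 3

    def test_fewer_than_three_series_rejected(self):
        table, _ = self.hand_table()
        table = table[table["subject"] == "s1"]
        table = table[(table["eye"] == "right") | (table["timepoint_min"] != 30)]
        with pytest.raises(ValueError, match=">= 3"), pytest.warns(UserWarning):
            rm_anova(table)


class TestRegression:
    def test_noiseless_line_recovered_exactly(self):
        ses = np.linspace(-6.0, 0.0, 8)
        rows = []
        for i, se in enumerate(ses):
            change = 1.44 * se - 11.8
            rows += [(f"s{i}", "right", "dark_text", 0, 250.0, se),
                     (f"s{i}", "right", "dark_text", 60, 250.0 + change, se)]
        res = regress_thinning_on_refraction(change_from_baseline(make_table(rows)))
        assert res.slope == pytest.approx(1.44, abs=1e-9)
        assert res.intercept == pytest.approx(-11.8, abs=1e-9)
        assert res.r == pytest.approx(1.0, abs=1e-9)

    def test_constant_change_gives_zero_slope_and_correlation(self):
        rows = []
        for i, se in enumerate((-4.0, -2.0, 0.0)):
            rows += [(f"s{i}", "right", "dark_text", 0, 250.0, se),
                     (f"s{i}", "right", "dark_text", 60, 245.0, se)]
        res = regress_thinning_on_refraction(change_from_baseline(make_table(rows)))
        assert res.slope == 0.0 and res.r == 0.0

    def test_identical_refractions_rejected(self):
        rows = []
        for i in range(4):
            rows += [(f"s{i}", "right", "dark_text", 0, 250.0, -3.0),
                     (f"s{i}", "right", "dark_text", 60, 240.0 + i, -3.0)]
        with pytest.raises(ValueError, match="identical"):
            regress_thinning_on_refraction(change_from_baseline(make_table(rows)))


class TestSimulateCohort:
    def test_zero_noise_zero_effect_reads_equal_baseline(self):
        spec = SynthCohortSpec(
            effect_60min_dark=0.0, effect_60min_light=0.0,
            between_subject_sd_dark=0.0, between_subject_sd_light=0.0,
            measurement_sd=0.0, baseline_sd=0.0, refraction_slope=0.0,
        )
        table = simulate_cohort(spec, seed=5)
        assert (table["thickness_um"] == spec.baseline_mean).all()

    def test_deterministic_per_seed(self):
        a, b = simulate_cohort(seed=42), simulate_cohort(seed=42)
        pd.testing.assert_frame_equal(a, b)
        assert not simulate_cohort(seed=43)["thickness_um"].equals(a["thickness_um"])

    def test_structure(self):
        table = simulate_cohort(seed=0)
        # 7 subjects x 2 eyes x 3 conditions x 3 timepoints x 5 reads
        assert len(table) == 7 * 2 * 3 * 3 * 5
        assert set(table["condition"]) == {"dark_text", "light_text", "blank_screen"}
        assert table["spherical_equivalent_d"].between(-6.25, 0.25).all()

    def test_blank_screen_has_no_systematic_change(self):
        means = []
        for seed in range(30):
            changes = change_from_baseline(simulate_cohort(seed=seed))
            means.append(condition_effect(changes, "blank_screen").mean)
        # SE of the grand mean ~ 7/sqrt(5*14*2)/sqrt(30) ~ 0.1 um
        assert np.mean(means) == pytest.approx(0.0, abs=0.5)

    def test_condition_effect_signs(self):
        changes = change_from_baseline(simulate_cohort(seed=1))
        assert condition_effect(changes, "dark_text").mean < 0
        assert condition_effect(changes, "light_text").mean > 0

    def test_thirty_minute_effect_is_half_of_sixty(self):
        spec = SynthCohortSpec(measurement_sd=0.0, baseline_sd=0.0)
        changes = change_from_baseline(simulate_cohort(spec, seed=9))
        by_t = changes[changes["condition"] == "dark_text"].groupby(
            "timepoint_min")["change_um"].mean()
        assert by_t[30] == pytest.approx(0.5 * by_t[60], abs=1e-9)

    def test_invalid_specs(self):
        with pytest.raises(ValueError):
            SynthCohortSpec(n_subjects=1)
        with pytest.raises(ValueError):
            SynthCohortSpec(measurement_sd=-1.0)


class TestPipeline:
    def test_detects_dark_text_thinning_reliably(self):
        """At the default effect sizes, a 7-subject cohort shows a
        significant 60-minute dark-text change in nearly every replicate."""
        hits = 0
        n = 40
        for seed in range(n):
            res = rm_anova(simulate_cohort(seed=seed), condition="dark_text")
            if res.followup[60] is not None and res.followup[60].p < 0.05:
                hits += 1
        assert hits >= 0.9 * n

    def test_stats_report_shape(self):
        report = stats_report(simulate_cohort(seed=2))
        conds = report["conditions"]
        assert set(conds) == {"dark_text", "light_text", "blank_screen"}
        assert conds["dark_text"]["change_60min"]["mean_um"] < 0
        assert conds["light_text"]["change_60min"]["mean_um"] > 0
        assert "refraction_regression" in conds["dark_text"]
        assert conds["dark_text"]["rm_anova"]["df_num"] == 2

    def test_subject_pooling_mode(self):
        changes = change_from_baseline(simulate_cohort(seed=3))
        eyes = condition_effect(changes, "dark_text", pooling="eyes")
        subj = condition_effect(changes, "dark_text", pooling="subjects")
        assert subj.n == 7 and eyes.n == 14
        assert subj.mean == pytest.approx(eyes.mean, abs=1e-9)  # balanced design


class TestTableIO:
    def test_csv_roundtrip(self, tmp_path):
        table = simulate_cohort(seed=4)
        path = tmp_path / "cohort.csv"
        save_measurements(table, path)
        loaded = load_measurements(path)
        assert len(loaded) == len(table)
        assert np.allclose(loaded["thickness_um"], table["thickness_um"], atol=1e-3)

    def test_excel_ingestion(self, tmp_path):
        """User-supplied spreadsheets load through the same entry point."""
        table = simulate_cohort(SynthCohortSpec(n_subjects=2), seed=4)
        path = tmp_path / "cohort.xlsx"
        table.to_excel(path, index=False)
        loaded = load_measurements(path)
        report = stats_report(loaded)
        assert "dark_text" in report["conditions"]

    def test_schema_violations_rejected(self, tmp_path):
        bad = simulate_cohort(seed=0).rename(columns={"thickness_um": "thick"})
        path = tmp_path / "bad.csv"
        bad.to_csv(path, index=False)
        with pytest.raises(ValueError, match="thickness_um"):
            load_measurements(path)
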