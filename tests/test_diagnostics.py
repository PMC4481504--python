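"""Confounder-criteria checks, the conventional comparator, descriptive tables,
and the chi-square independence test against a brute-force oracle."""

import numpy as np
import pandas as pd
import pytest

import weightmsm as wm
from weightmsm import diagnostics
from weightmsm.cohort import default_params


def brute_force_chi_square(table):
    """Independent oracle: expected counts via explicit margin loops."""
    table = np.asarray(table, dtype=float)
    r, c = table.shape
    total = table.sum()
    stat = 0.0
    for i in range(r):
        for j in range(c):
            expected = table[i].sum() * table[:, j].sum() / total
            stat += (table[i, j] - expected) ** 2 / expected
    return stat, (r - 1) * (c - 1)


class TestChiSquare:
    def test_perfect_independence(self):
        stat, df, p = wm.chi_square_independence([[10, 10], [10, 10]])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_two_by_two(self):
        stat, df, p = wm.chi_square_independence([[20, 10], [10, 20]])
        assert stat == pytest.approx(20.0 / 3.0)
        assert df == 1

    def test_agrees_with_brute_force_on_random_tables(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            shape = (rng.integers(2, 6), rng.integers(2, 6))
            table = rng.integers(1, 60, size=shape)
            stat, df, _ = wm.chi_square_independence(table)
            bstat, bdf = brute_force_chi_square(table)
            assert stat == pytest.approx(bstat, rel=1e-10)
            assert df == bdf

    @pytest.mark.parametrize("bad", [
        [[5, 5]],                       # single row
        [[0, 0], [3, 4]],               # zero margin
        [[-1, 2], [3, 4]],              # negative count
    ])
    def test_invalid_tables_rejected(self, bad):
        with pytest.raises(ValueError):
            wm.chi_square_independence(bad)


class TestConfoundingChecks:
    def test_confounded_world_flags_all_three_criteria(self, person_periods):
        rep = wm.confounding_checks(person_periods)
        assert rep.health_to_weight_change.association is True
        assert rep.health_to_mortality.association is True
        assert rep.weight_change_to_health.association is True

    def test_no_feedback_world_passes_reverse_check(self):
        panel = wm.simulate_cohort(default_params("no_feedback",
                                                  n_subjects=3000, seed=19))
        pp, _ = wm.prepare(panel)
        rep = wm.confounding_checks(pp)
        assert rep.health_to_weight_change.association is True
        assert rep.health_to_mortality.association is True
        assert rep.weight_change_to_health.association is False

    def test_degenerate_alpha_flags_everything(self, person_periods):
        rep = wm.confounding_checks(person_periods, alpha=1.0)
        assert all(b.association for b in rep.blocks().values())

    def test_blocks_name_outcome_and_regressors(self, person_periods):
        rep = wm.confounding_checks(person_periods)
        for block in rep.blocks().values():
            assert block.outcome and block.regressors and block.n_rows > 0
            assert {"unadjusted", "adjusted"} <= set(block.variants)


class TestNaiveComparator:
    def test_weight_column_ignored_with_warning(self, person_periods, weight_set):
        pp = person_periods.copy()
        pp["weight"] = weight_set.final
        with pytest.warns(UserWarning, match="unweighted"):
            res = diagnostics.fit_naive_timedep(pp)
        unweighted = diagnostics.fit_naive_timedep(person_periods)
        pd.testing.assert_series_equal(res.params, unweighted.params)

    def test_result_shape_matches_msm(self, person_periods):
        res = diagnostics.fit_naive_timedep(person_periods)
        assert {"exposure[LargeLoss]", "base_bmi_cat[Underweight]"} <= set(res.params.index)
        assert res.n_events == person_periods["event"].sum()

    def test_matches_msm_without_confounding(self):
        p = default_params("no_feedback", n_subjects=4000, seed=23)
        for cat in p.exposure_coefs.values():
            for k in ("lag_illness", "lag_poor_srh", "lag_smoke_current",
                      "lag_smoke_former", "lag_vig"):
                cat[k] = 0.0
        panel = wm.simulate_cohort(p)
        res_msm = wm.run_msm_pipeline(panel, design="M4")
        pp, _ = wm.prepare(panel)
        res_naive = diagnostics.fit_naive_timedep(pp, design="M4")
        for lv in ("LargeLoss", "SmallLoss"):
            name = f"exposure[{lv}]"
            diff = abs(res_msm.params[name] - res_naive.params[name])
            tol = 3.0 * np.hypot(res_msm.robust_se[name], res_naive.robust_se[name])
            assert diff < tol


class TestBaselineTable:
    def _panel(self, trajectories):
        rows = []
        for sid, bmis in trajectories.items():
            for t, b in enumerate(bmis, start=1):
                rows.append(dict(
                    subject_id=sid, wave=t, bmi=b, age=55.0, female=1,
                    race="white", education="highschool", marital_status="married",
                    log_income=10.8, illness_ever=0, illness_new=0, srh_good=1,
                    smoking="never", vig_activity=0, alive_at_wave=1,
                    died_in_interval=0, censored_in_interval=0))
        return pd.DataFrame(rows)

    def test_always_stable_subject_in_stable_column_only(self):
        tab = diagnostics.baseline_table(self._panel({1: [24.0, 24.2, 24.1]}))
        assert tab.loc["n_subjects", "whole_sample"] == 1
        assert tab.loc["n_subjects", "stable_all"] == 1
        assert tab.loc["n_subjects", "ever_LargeLoss"] == 0

    def test_subject_appears_in_multiple_change_columns(self):
        tab = diagnostics.baseline_table(self._panel({1: [24.0, 21.0, 22.5]}))
        # -12.5% then +7.1%: both a large loss and a small gain
        assert tab.loc["n_subjects", "ever_LargeLoss"] == 1
        assert tab.loc["n_subjects", "ever_SmallGain"] == 1
        assert tab.loc["n_subjects", "stable_all"] == 0

    def test_categorical_blocks_close_to_hundred(self, confounded_panel):
        tab = diagnostics.baseline_table(confounded_panel)
        for block in ("race", "education", "marital", "smoking"):
            rows = [r for r in tab.index if r.startswith(f"{block}:")]
            sums = tab.loc[rows].sum()
            assert np.allclose(sums, 100.0, atol=0.5), (block, sums)

    def test_membership_reproducible_by_independent_recount(self, confounded_panel):
        tab = diagnostics.baseline_table(confounded_panel)
        panel = confounded_panel.sort_values(["subject_id", "wave"])
        count = 0
        for _, sub in panel.groupby("subject_id"):
            b = sub["bmi"].to_numpy(dtype=float)
            pct = 100.0 * np.diff(b) / b[:-1]
            if np.any(pct[~np.isnan(pct)] <= -10.0):
                count += 1
        assert tab.loc["n_subjects", "ever_LargeLoss"] == count


def test_weight_change_by_health_association(person_periods):
    tab = diagnostics.weight_change_by_health_table(person_periods)
    assert list(tab.index) == list(wm.cohort.WC_LEVELS)
    for col in tab.columns:
        assert tab[col].sum() == pytest.approx(100.0)
    for stat, p in tab.attrs["chi_square"].values():
        assert p < 0.001
    # losses concentrate after diagnosis / poor health
    assert tab.loc["LargeLoss", "diagnosis"] > tab.loc["LargeLoss", "no_diagnosis"]
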