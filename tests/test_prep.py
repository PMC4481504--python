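"""Categorization boundaries, the exclusion cascade, and person-period expansion."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import weightmsm as wm
from weightmsm.cohort import BMI_LEVELS, WC_LEVELS
from weightmsm.prep import ExclusionReport, apply_exclusions, build_person_periods


class TestComputeBMI:
    def test_hand_computed_value(self):
        assert wm.compute_bmi(81.0, 1.80) == pytest.approx(25.0)

    def test_unit_height(self):
        assert wm.compute_bmi(18.5, 1.0) == pytest.approx(18.5)

    @pytest.mark.parametrize("w,h", [(0.0, 1.7), (70.0, 0.0), (-1.0, 1.7)])
    def test_nonpositive_inputs_rejected(self, w, h):
        with pytest.raises(ValueError):
            wm.compute_bmi(w, h)


class TestCategorizeBMI:
    @pytest.mark.parametrize("bmi,expected", [
        (14.0, "Underweight"), (18.4, "Underweight"),
        (18.5, "Normal"), (24.999, "Normal"),
        (25.0, "Overweight"), (29.999, "Overweight"),
        (30.0, "ObeseI"), (34.999, "ObeseI"),
        (35.0, "ObeseII_III"), (60.0, "ObeseII_III"),
    ])
    def test_who_boundaries(self, bmi, expected):
        assert wm.categorize_bmi(bmi) == expected

    def test_missing_propagates(self):
        out = wm.categorize_bmi(pd.Series([22.0, np.nan]))
        assert out.iloc[0] == "Normal" and out.iloc[1] is None

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            wm.categorize_bmi(0.0)


class TestPctChange:
    @pytest.mark.parametrize("prev,curr,expected", [
        (30.0, 27.0, -10.0), (24.0, 24.0, 0.0), (20.0, 22.0, 10.0),
    ])
    def test_hand_arithmetic(self, prev, curr, expected):
        assert wm.pct_bmi_change(prev, curr) == pytest.approx(expected)

    def test_nonpositive_previous_rejected(self):
        with pytest.raises(ValueError):
            wm.pct_bmi_change(0.0, 25.0)


class TestCategorizeWeightChange:
    @pytest.mark.parametrize("p,expected", [
        (-30.0, "LargeLoss"), (-12.0, "LargeLoss"), (-10.0, "LargeLoss"),
        (-9.999, "SmallLoss"), (-5.0, "SmallLoss"),
        (-4.999, "Stable"), (0.0, "Stable"), (4.999, "Stable"),
        (5.0, "SmallGain"), (9.999, "SmallGain"),
        (10.0, "LargeGain"), (25.0, "LargeGain"),
    ])
    def test_boundary_conventions(self, p, expected):
        assert wm.categorize_weight_change(p) == expected

    @given(st.floats(min_value=-60.0, max_value=60.0,
                     allow_nan=False, allow_infinity=False))
    @settings(max_examples=300, deadline=None)
    def test_total_and_mutually_exclusive(self, p):
        assert wm.categorize_weight_change(p) in WC_LEVELS

    @given(st.floats(min_value=5.0, max_value=80.0, allow_nan=False))
    @settings(max_examples=100, deadline=None)
    def test_bmi_maps_to_exactly_one_category(self, bmi):
        assert wm.categorize_bmi(bmi) in BMI_LEVELS


def _panel_row(sid, wave, bmi, died=0, cens=0):
    return dict(subject_id=sid, wave=wave, bmi=bmi,
                died_in_interval=died, censored_in_interval=cens)


def _clean_subject(sid, bmis, died_at=None, cens_at=None):
    rows = []
    for t, b in enumerate(bmis, start=1):
        died = 1 if died_at == t else 0
        cens = 1 if cens_at == t else 0
        rows.append(_panel_row(sid, t, b, died, cens))
        if died or cens:
            break
    return rows


@pytest.fixture
def ten_subject_panel():
    """Exactly one subject violating each exclusion rule plus five clean ones."""
    rows = []
    rows += _clean_subject(1, [24.0], died_at=1)                    # died before wave 2
    rows += _clean_subject(2, [24.0], cens_at=1)                    # dropped before wave 2
    rows += _clean_subject(3, [24.0, np.nan, 25.0])                 # missing BMI
    rows += _clean_subject(4, [61.0, 60.0, 59.0])                   # baseline BMI > 60
    rows += _clean_subject(5, [24.0, 16.0, 16.0])                   # -33% between waves
    for sid in range(6, 11):
        rows += _clean_subject(sid, [24.0 + sid * 0.1, 25.0, 26.0])
    return pd.DataFrame(rows)


class TestExclusions:
    def test_empty_panel(self):
        empty = pd.DataFrame(columns=["subject_id", "wave", "bmi",
                                      "died_in_interval", "censored_in_interval"])
        out, rep = apply_exclusions(empty)
        assert len(out) == 0
        assert rep.n_retained_subjects == 0
        assert all(v == 0 for v in rep.counts.values())

    def test_constructed_fixture_counts(self, ten_subject_panel):
        out, rep = apply_exclusions(ten_subject_panel)
        assert rep.n_input_subjects == 10
        assert rep.n_retained_subjects == 5
        assert all(v == 1 for v in rep.counts.values()), rep.counts

    def test_extreme_loss_rule(self):
        rows = _clean_subject(1, [24.0, 16.0, 16.0]) + _clean_subject(2, [24.0, 23.0, 22.0])
        out, rep = apply_exclusions(pd.DataFrame(rows))
        assert rep.counts["extreme_loss_gt_30pct"] == 1
        assert set(out["subject_id"]) == {2}

    def test_idempotent(self, confounded_panel):
        once, rep1 = apply_exclusions(confounded_panel)
        twice, rep2 = apply_exclusions(once)
        pd.testing.assert_frame_equal(once.reset_index(drop=True),
                                      twice.reset_index(drop=True))
        assert rep2.n_retained_subjects == rep1.n_retained_subjects
        assert all(v == 0 for v in rep2.counts.values())

    def test_missing_columns_named(self):
        with pytest.raises(ValueError, match="bmi"):
            apply_exclusions(pd.DataFrame({"subject_id": [1], "wave": [1]}))

    def test_report_arithmetic_invariant(self, ten_subject_panel):
        _, rep = apply_exclusions(ten_subject_panel)
        assert rep.n_retained_subjects == rep.n_input_subjects - sum(rep.counts.values())


def _full_subject(sid, bmis, **kw):
    """A subject with the covariate columns person-period expansion needs."""
    rows = _clean_subject(sid, bmis, **kw)
    for i, r in enumerate(rows):
        r.update(age=55.0 + 2 * i, female=1, race="white", education="highschool",
                 marital_status="married", log_income=10.8,
                 illness_ever=0 if i < 2 else 1, illness_new=1 if i == 2 else 0,
                 srh_good=1, smoking="never" if i else "current",
                 vig_activity=0, alive_at_wave=1)
    return rows


class TestPersonPeriods:
    def test_four_waves_no_event_gives_three_intervals(self):
        pp = build_person_periods(pd.DataFrame(_full_subject(1, [24, 24.5, 25, 25.5])))
        assert len(pp) == 3
        assert list(pp["interval"]) == [2, 3, 4]
        assert pp["event"].sum() == 0

    def test_death_interval_is_last_row(self):
        pp = build_person_periods(
            pd.DataFrame(_full_subject(1, [24, 24.5, 25, 25.5], died_at=3)))
        assert list(pp["interval"]) == [2, 3]
        assert pp.iloc[-1]["event"] == 1

    def test_covariates_lagged_one_interview(self):
        pp = build_person_periods(pd.DataFrame(_full_subject(1, [24, 24.5, 25])))
        # wave-1 smoking was "current"; the t=2 row must carry it
        assert pp.loc[pp["interval"] == 2, "lag_smoking"].item() == "current"
        assert pp.loc[pp["interval"] == 3, "lag_smoking"].item() == "never"

    def test_exposure_from_consecutive_bmi(self):
        pp = build_person_periods(pd.DataFrame(_full_subject(1, [24.0, 21.0, 22.5])))
        assert list(pp["exposure"]) == ["LargeLoss", "SmallGain"]
        assert list(pp["prior_exposure"]) == ["none", "LargeLoss"]

    def test_gap_counts_as_dropout(self):
        rows = _full_subject(1, [24, 24.5, 25, 25.5])
        df = pd.DataFrame([r for r in rows if r["wave"] != 3])
        pp = build_person_periods(df)
        assert list(pp["interval"]) == [2]
        assert pp.iloc[-1]["censor"] == 1

    def test_nonmonotone_waves_rejected(self):
        df = pd.DataFrame(_full_subject(1, [24, 24.5, 25]))
        df.loc[2, "wave"] = 2
        with pytest.raises(ValueError, match="increasing"):
            build_person_periods(df)

    def test_accounting_on_simulated_cohort(self, confounded_panel, person_periods):
        filtered, _ = apply_exclusions(confounded_panel)
        deaths = filtered.groupby("subject_id")["died_in_interval"].max().sum()
        assert person_periods["event"].sum() == deaths
        per_subject = person_periods.groupby("subject_id").size()
        attended = filtered.groupby("subject_id")["wave"].count()
        assert (per_subject == attended.loc[per_subject.index] - 1).all()

    def test_exposure_never_missing(self, person_periods):
        assert person_periods["exposure"].notna().all()
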