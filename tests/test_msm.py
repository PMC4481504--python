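"""The weighted pooled hazard model: arithmetic, invariances, stratified and
interaction fits, and agreement with a continuous-time comparator."""

import re

import numpy as np
import pandas as pd
import pytest

import weightmsm as wm
from weightmsm import msm
from weightmsm.cohort import default_params
from weightmsm.exceptions import UnestimableModel


def test_hr_and_ci_arithmetic():
    tab = msm._hr_frame(pd.Series({"b": 0.693}), pd.Series({"b": 0.05}))
    assert tab.loc["b", "HR"] == pytest.approx(2.00, abs=0.005)
    assert tab.loc["b", "ci_low"] == pytest.approx(1.81, abs=0.005)
    assert tab.loc["b", "ci_high"] == pytest.approx(2.21, abs=0.005)


def test_zero_coefficient_renders_unit_hazard_ratio():
    res = msm.MSMResult(
        label="M1", params=pd.Series({"base_bmi_cat[Overweight]": 0.0}),
        cov=pd.DataFrame(), robust_se=pd.Series({"base_bmi_cat[Overweight]": 0.1}),
        hr_table=msm._hr_frame(pd.Series({"base_bmi_cat[Overweight]": 0.0}),
                               pd.Series({"base_bmi_cat[Overweight]": 0.1})),
        n_subjects=1, n_person_periods=1, n_events=1, weight_summary={})
    cell = msm.hazard_ratio_table([res]).loc["Overweight", "M1"]
    assert cell.startswith("1.00 ")


@pytest.fixture(scope="module")
def sequence_results(confounded_panel):
    return wm.model_sequence(confounded_panel)


def test_model_sequence_table_shape_and_format(sequence_results):
    tab = msm.hazard_ratio_table(sequence_results)
    assert tab.shape == (8, 4)
    assert list(tab.columns) == ["M1", "M2", "M3", "M4"]
    cell = tab.loc["Weight Loss 10%+", "M4"]
    assert re.match(r"^\d+\.\d{2}\*{0,3} \(\d+\.\d{2}, \d+\.\d{2}\)$", cell)


def test_confounding_adjustment_moves_loss_estimates_down(sequence_results):
    """The unadjusted column overstates the large-loss hazard relative to the
    fully weighted model, the direction the confounding structure implies."""
    m1, m4 = sequence_results[0], sequence_results[3]
    assert m1.hr("exposure[LargeLoss]") > m4.hr("exposure[LargeLoss]")


def test_row_order_and_subject_labels_irrelevant(person_periods, weight_set):
    base = wm.fit_msm(person_periods, weights=weight_set, design="M4")
    rng = np.random.default_rng(0)
    perm = rng.permutation(len(person_periods))
    pp2 = person_periods.iloc[perm].reset_index(drop=True)
    pp2["subject_id"] = pp2["subject_id"] + 10_000
    w2 = weight_set.final.to_numpy()[perm]
    other = wm.fit_msm(pp2, weights=w2, design="M4")
    pd.testing.assert_series_equal(base.params, other.params, atol=1e-8, rtol=1e-6)


def test_all_ones_weights_equal_unweighted(person_periods):
    a = wm.fit_msm(person_periods, weights=np.ones(len(person_periods)), design="M4")
    b = wm.fit_msm(person_periods, weights=None, design="M4")
    pd.testing.assert_series_equal(a.params, b.params, atol=1e-10, rtol=1e-8)


def test_no_events_in_category_raises(person_periods):
    pp = person_periods.copy()
    pp.loc[pp["exposure"] == "SmallGain", "event"] = 0
    with pytest.raises(UnestimableModel, match="SmallGain"):
        wm.fit_msm(pp, weights=None, design="M4")


def test_pooled_logistic_tracks_continuous_time_hazard_model():
    """With rare interval events the pooled logistic HRs agree with a
    counting-process proportional-hazards fit on the same data."""
    from lifelines import CoxTimeVaryingFitter

    p = default_params("no_feedback", n_subjects=4000, seed=31)
    for cat in p.exposure_coefs.values():
        for k in ("lag_illness", "lag_poor_srh", "lag_smoke_current",
                  "lag_smoke_former", "lag_vig"):
            cat[k] = 0.0
    pp, _ = wm.prepare(wm.simulate_cohort(p))
    # exposure terms only on both sides: the sparse underweight cell makes the
    # partial-likelihood fit singular, and exposure is independent of everything
    pooled = wm.fit_msm(pp, weights=None, design="M1", include_bmi=False)

    df = pp[["subject_id", "event"]].copy()
    df["start"] = pp["interval"] - 1.0
    df["stop"] = pp["interval"].astype(float)
    for lv in ("LargeLoss", "SmallLoss", "SmallGain", "LargeGain"):
        df[lv] = (pp["exposure"] == lv).astype(float)
    ctv = CoxTimeVaryingFitter()
    ctv.fit(df, id_col="subject_id", start_col="start", stop_col="stop",
            event_col="event")
    for lv in ("LargeLoss", "SmallLoss", "LargeGain"):
        hr_pooled = pooled.hr(f"exposure[{lv}]")
        hr_cox = float(np.exp(ctv.params_[lv]))
        assert abs(hr_pooled / hr_cox - 1.0) < 0.05, (lv, hr_pooled, hr_cox)


class TestStratified:
    def test_smoking_strata_estimable_and_similar(self, person_periods):
        out = msm.stratified_fit(person_periods, "smoking_ever")
        assert set(out) == {"ever", "never"}
        assert all(isinstance(v, msm.MSMResult) for v in out.values())
        # the generator gives both strata the same structural effects
        diff = abs(out["ever"].params["exposure[LargeLoss]"]
                   - out["never"].params["exposure[LargeLoss]"])
        tol = 3.0 * np.hypot(out["ever"].robust_se["exposure[LargeLoss]"],
                             out["never"].robust_se["exposure[LargeLoss]"])
        assert diff < tol

    def test_baseline_bmi_strata_drop_bmi_terms(self, person_periods):
        out = msm.stratified_fit(person_periods, "baseline_bmi_category",
                                 collapse_obesity=True)
        assert set(out) <= {"Underweight", "Normal", "Overweight", "Obese"}
        estimable = {k: v for k, v in out.items() if isinstance(v, msm.MSMResult)}
        assert {"Normal", "Overweight", "Obese"} <= set(estimable)
        for v in estimable.values():
            assert not any(c.startswith("base_bmi_cat[") for c in v.params.index)

    def test_tiny_stratum_flagged_not_fatal(self, person_periods):
        sub = person_periods[person_periods["subject_id"] % 17 == 0]
        out = msm.stratified_fit(sub, "baseline_bmi_category")
        assert any(isinstance(v, str) and "unestimable" in v for v in out.values())

    def test_unknown_stratifier_rejected(self, person_periods):
        with pytest.raises(ValueError, match="stratifier"):
            msm.stratified_fit(person_periods, "income")


class TestInteractions:
    def test_smoking_interaction_table(self, person_periods, weight_set):
        tab = msm.interaction_fit(person_periods, weight_set, "smoking_ever")
        assert len(tab) == 8  # 4 exposure + 4 baseline-BMI interactions
        assert ((tab["p"] > 0) & (tab["p"] <= 1)).all()
        assert "joint_wald" in tab.attrs
        # no effect modification in the generator: the joint test should not
        # reject overwhelmingly on this fixture
        assert tab.attrs["joint_wald"]["p"] > 0.01

    def test_bmi_interaction_collapses_obesity(self, person_periods, weight_set):
        tab = msm.interaction_fit(person_periods, weight_set,
                                  "baseline_bmi_category", collapse_obesity=True)
        assert len(tab) == 12  # 3 non-reference BMI levels x 4 exposure levels
        assert all(":" in name for name in tab.index)

    def test_constant_interactor_rejected(self, person_periods):
        pp = person_periods.copy()
        pp["base_smoking"] = "never"
        with pytest.raises(UnestimableModel, match="smoking_ever"):
            msm.interaction_fit(pp, None, "smoking_ever")
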