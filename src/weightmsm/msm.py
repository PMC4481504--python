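"""Weighted discrete-time pooled hazard models for the marginal structural analysis.

The outcome model is a pooled logistic regression of the interval death indicator on
interval dummies (the discrete baseline hazard), the four weight-change dummies
(Stable reference), the four baseline-BMI dummies (Normal reference) and a
design-specific set of baseline covariates, with the stabilized weights supplied as
frequency weights and a subject-clustered sandwich covariance.  With biennial
intervals and rare per-interval events the exponentiated coefficients are hazard
ratios in the proportional-hazards sense.

The four model designs form an incremental sequence: M1 is unweighted with no
baseline covariates beyond weight terms; M2 adds socio-demographic/SES covariates
(baseline values in the outcome model, lagged SES in the weight denominator); M3
adds health behaviors (smoking, physical activity); M4 adds health conditions
(chronic illness, self-rated health).  Time-varying confounders never enter the
outcome model directly — conditioning on them would adjust away the part of the
weight-change effect they mediate; they act through the weights alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohort import BMI_LEVELS, SMOKING_LEVELS, WC_LEVELS
from .design import CovariateSpec, dmatrix, dummy_name
from .exceptions import (PositivityViolation, SpecificationError,
                         UnestimableModel)
from .weights import _DEMOGRAPHICS, DESIGN_BLOCKS

MODEL_DESIGNS = ("M1", "M2", "M3", "M4")

_BEHAVIOR_BASE = CovariateSpec(
    numeric=("base_vig",),
    categorical={"base_smoking": (SMOKING_LEVELS, "never")},
)
_CONDITION_BASE = CovariateSpec(numeric=("base_illness", "base_srh_good"))


def outcome_baseline_spec(design: str) -> CovariateSpec:
    """Baseline covariates entering the outcome model under each design."""
    if design not in MODEL_DESIGNS:
        raise ValueError(f"design must be one of {MODEL_DESIGNS}")
    spec = CovariateSpec()
    if design in ("M2", "M3", "M4"):
        spec = spec.merge(_DEMOGRAPHICS)
    if design in ("M3", "M4"):
        spec = spec.merge(_BEHAVIOR_BASE)
    if design == "M4":
        spec = spec.merge(_CONDITION_BASE)
    return spec


@dataclass
class MSMResult:
    """One fitted pooled hazard model: estimates, robust covariance, HR table."""

    label: str
    params: pd.Series
    cov: pd.DataFrame
    robust_se: pd.Series
    hr_table: pd.DataFrame  # HR, ci_low, ci_high, p per coefficient
    n_subjects: int
    n_person_periods: int
    n_events: int
    weight_summary: dict
    converged: bool = True

    def hr(self, name: str) -> float:
        return float(self.hr_table.loc[name, "HR"])


def _hr_frame(params: pd.Series, se: pd.Series) -> pd.DataFrame:
    z = params / se
    return pd.DataFrame({
        "logHR": params,
        "se": se,
        "HR": np.exp(params),
        "ci_low": np.exp(params - 1.96 * se),
        "ci_high": np.exp(params + 1.96 * se),
        "p": 2 * stats.norm.sf(np.abs(z)),
    })


def _check_events(pp: pd.DataFrame, by: str = "exposure") -> None:
    counts = pp.groupby(by, observed=True)["event"].agg(["size", "sum"])
    levels = WC_LEVELS if by == "exposure" else sorted(pp[by].unique())
    for lv in levels:
        if lv not in counts.index or counts.loc[lv, "size"] == 0:
            raise UnestimableModel(f"no person-periods in {by} category {lv!r}")
        if counts.loc[lv, "sum"] == 0:
            raise UnestimableModel(f"no events in {by} category {lv!r}")


def _interval_spec(pp: pd.DataFrame) -> CovariateSpec:
    levels = tuple(str(t) for t in sorted(pp["interval"].unique()))
    return CovariateSpec(categorical={"interval_f": (levels, levels[0])})


def _outcome_design(pp: pd.DataFrame, design: str, include_bmi: bool = True,
                    extra: pd.DataFrame | None = None,
                    baseline_spec: CovariateSpec | None = None) -> pd.DataFrame:
    pp = pp.copy()
    pp["interval_f"] = pp["interval"].astype(str)
    spec = _interval_spec(pp).merge(
        CovariateSpec(categorical={"exposure": (WC_LEVELS, "Stable")})
    )
    if include_bmi:
        spec = spec.merge(
            CovariateSpec(categorical={"base_bmi_cat": (tuple(sorted(set(pp["base_bmi_cat"]), key=list(BMI_LEVELS).index)), "Normal")})
        )
    spec = spec.merge(outcome_baseline_spec(design) if baseline_spec is None
                      else baseline_spec)
    X = dmatrix(pp, spec)
    if extra is not None:
        X = pd.concat([X, extra.set_index(X.index)], axis=1)
    return X


def _fit_pooled_logistic(y, X: pd.DataFrame, weights=None, groups=None):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(np.asarray(y, dtype=float), X.to_numpy(),
                       family=sm.families.Binomial(),
                       freq_weights=(None if weights is None else np.asarray(weights, dtype=float)))
        if groups is not None:
            res = model.fit(cov_type="cluster",
                            cov_kwds={"groups": np.asarray(groups)})
        else:
            res = model.fit()
    if not res.converged:
        raise UnestimableModel("pooled logistic outcome model did not converge "
                               "(possible separation)")
    if not np.all(np.isfinite(res.bse)):
        raise UnestimableModel("non-finite standard errors (possible separation)")
    return res


def fit_msm(person_periods: pd.DataFrame, weights=None, design: str = "M4",
            label: str | None = None, include_bmi: bool = True,
            cluster_robust: bool = True, collapse_obesity: bool = False,
            baseline_spec: CovariateSpec | None = None) -> MSMResult:
    """Fit one weighted pooled hazard model.

    ``weights`` may be a WeightSet, a Series/array of final weights, or ``None``
    (all-ones, the unweighted fit).  ``collapse_obesity`` merges the two obesity
    levels of baseline BMI into one dummy.
    """
    pp = person_periods
    _check_events(pp)
    if collapse_obesity and include_bmi:
        pp = pp.copy()
        pp["base_bmi_cat"] = pp["base_bmi_cat"].replace(
            {"ObeseI": "Obese", "ObeseII_III": "Obese"})
    w = None
    weight_summary = {"mean": 1.0, "all_ones": True}
    if weights is not None:
        w = weights.final if hasattr(weights, "final") else pd.Series(np.asarray(weights, dtype=float))
        w = np.asarray(w, dtype=float)
        if w.shape[0] != len(pp):
            raise ValueError("weights length does not match person-period rows")
        if np.any(w <= 0):
            raise ValueError("weights must be strictly positive")
        weight_summary = {"mean": float(w.mean()), "sd": float(w.std(ddof=0)),
                          "max": float(w.max()), "all_ones": bool(np.allclose(w, 1.0))}

    if collapse_obesity and include_bmi:
        spec_levels = tuple(lv for lv in ("Underweight", "Normal", "Overweight", "Obese")
                            if lv in set(pp["base_bmi_cat"]))
        pp2 = pp.copy()
        pp2["interval_f"] = pp2["interval"].astype(str)
        spec = _interval_spec(pp2).merge(
            CovariateSpec(categorical={"exposure": (WC_LEVELS, "Stable"),
                                       "base_bmi_cat": (spec_levels, "Normal")})
        ).merge(outcome_baseline_spec(design) if baseline_spec is None
                else baseline_spec)
        X = dmatrix(pp2, spec)
    else:
        X = _outcome_design(pp, design, include_bmi=include_bmi,
                            baseline_spec=baseline_spec)
    res = _fit_pooled_logistic(
        pp["event"], X, weights=w,
        groups=pp["subject_id"] if cluster_robust else None,
    )
    params = pd.Series(res.params, index=X.columns)
    se = pd.Series(res.bse, index=X.columns)
    cov = pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns)
    return MSMResult(
        label=label or design,
        params=params, cov=cov, robust_se=se,
        hr_table=_hr_frame(params, se),
        n_subjects=int(pp["subject_id"].nunique()),
        n_person_periods=len(pp),
        n_events=int(pp["event"].sum()),
        weight_summary=weight_summary,
    )


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


#: display order and labels for the eight reported parameters
REPORT_ROWS = [
    (dummy_name("exposure", "LargeLoss"), "Weight Loss 10%+"),
    (dummy_name("exposure", "SmallLoss"), "Weight Loss 5-10%"),
    (dummy_name("exposure", "SmallGain"), "Weight Gain 5-10%"),
    (dummy_name("exposure", "LargeGain"), "Weight Gain 10%+"),
    (dummy_name("base_bmi_cat", "Underweight"), "Underweight"),
    (dummy_name("base_bmi_cat", "Overweight"), "Overweight"),
    (dummy_name("base_bmi_cat", "ObeseI"), "Obese I"),
    (dummy_name("base_bmi_cat", "ObeseII_III"), "Obese II/III"),
]


def hazard_ratio_table(results: list[MSMResult]) -> pd.DataFrame:
    """Render a models-in-columns table: ``HR*** (low, high)`` per cell."""
    if not results:
        raise ValueError("at least one MSMResult is required")
    out = {}
    for res in results:
        col = {}
        for name, rowlabel in REPORT_ROWS:
            if name not in res.hr_table.index:
                col[rowlabel] = "-"
                continue
            r = res.hr_table.loc[name]
            col[rowlabel] = (f"{r['HR']:.2f}{_stars(r['p'])} "
                             f"({r['ci_low']:.2f}, {r['ci_high']:.2f})")
        out[res.label] = col
    return pd.DataFrame(out)


def _smoking_ever(pp: pd.DataFrame) -> pd.Series:
    return np.where(pp["base_smoking"] == "never", "never", "ever")


def stratified_fit(person_periods: pd.DataFrame, stratifier: str,
                   design: str = "M4", collapse_obesity: bool = False,
                   censor_weights: bool = True,
                   truncation=(1.0, 99.0)) -> dict[str, MSMResult | str]:
    """Refit weights and outcome model within each stratum.

    ``stratifier`` is ``smoking_ever`` or ``baseline_bmi_category``; for the latter
    the baseline-BMI dummies are dropped from the outcome model and the two obesity
    levels may be collapsed.  A stratum whose fit fails (empty category, no events)
    is reported with the error message instead of failing globally.
    """
    from .weights import compute_stabilized_weights, fit_censoring_models, fit_exposure_models

    pp = person_periods.copy()
    if stratifier == "smoking_ever":
        key = pd.Series(_smoking_ever(pp), index=pp.index)
        include_bmi = True
    elif stratifier == "baseline_bmi_category":
        key = pp["base_bmi_cat"].copy()
        if collapse_obesity:
            key = key.replace({"ObeseI": "Obese", "ObeseII_III": "Obese"})
        include_bmi = False
    else:
        raise ValueError("stratifier must be 'smoking_ever' or 'baseline_bmi_category'")

    order = (["ever", "never"] if stratifier == "smoking_ever"
             else [lv for lv in ("Underweight", "Normal", "Overweight", "Obese",
                                 "ObeseI", "ObeseII_III") if lv in set(key)])
    from .design import prune
    from .weights import denominator_spec, numerator_spec

    results: dict[str, MSMResult | str] = {}
    for stratum in order:
        sub = pp[key == stratum]
        try:
            # stratum-constant covariates (e.g. baseline smoking within a smoking
            # stratum) are inestimable by construction and pruned from the refits
            den = prune(denominator_spec(design), sub, keep=("prior_exposure",))
            num = prune(numerator_spec(), sub, keep=("prior_exposure",))
            pair = fit_exposure_models(sub, denominator=den, numerator=num)
            cens = None
            if censor_weights and sub["censor"].sum() > 0:
                cens = fit_censoring_models(sub, den_spec=den, num_spec=num)
            ws = compute_stabilized_weights(sub, pair, censor_models=cens,
                                           truncation=truncation)
            results[stratum] = fit_msm(
                sub, weights=ws, design=design, label=stratum,
                include_bmi=include_bmi,
                baseline_spec=prune(outcome_baseline_spec(design), sub))
        except (UnestimableModel, SpecificationError, PositivityViolation,
                ValueError) as err:
            results[stratum] = f"unestimable: {err}"
    return results


def interaction_fit(person_periods: pd.DataFrame, weights, interactor: str,
                    design: str = "M4", collapse_obesity: bool = True) -> pd.DataFrame:
    """Single pooled model with interactor x (exposure, baseline-BMI) terms.

    Returns the interaction coefficient table with Wald p-values from the
    subject-clustered covariance, plus a joint Wald test row.
    """
    pp = person_periods.copy()
    if interactor == "smoking_ever":
        mod = pd.Series((_smoking_ever(pp) == "ever").astype(float), index=pp.index,
                        name="ever_smoker")
        include_bmi = True
        bmi_for_interaction = True
    elif interactor == "baseline_bmi_category":
        if collapse_obesity:
            pp["base_bmi_cat"] = pp["base_bmi_cat"].replace(
                {"ObeseI": "Obese", "ObeseII_III": "Obese"})
        mod = None
        include_bmi = True
        bmi_for_interaction = False
    else:
        raise ValueError("interactor must be 'smoking_ever' or 'baseline_bmi_category'")

    if interactor == "smoking_ever" and mod.nunique() < 2:
        raise UnestimableModel("interactor 'smoking_ever' is constant in these data")
    if interactor == "baseline_bmi_category" and pp["base_bmi_cat"].nunique() < 2:
        raise UnestimableModel("interactor 'baseline_bmi_category' is constant in these data")

    pp["interval_f"] = pp["interval"].astype(str)
    bmi_levels = tuple(sorted(set(pp["base_bmi_cat"]),
                              key=lambda lv: (list(BMI_LEVELS) + ["Obese"]).index(lv)))
    base_spec = outcome_baseline_spec(design)
    if interactor == "smoking_ever":
        # the ever-smoker indicator replaces the three-level smoking factor,
        # which it would otherwise be collinear with
        base_spec = base_spec.drop("base_smoking")
    spec = _interval_spec(pp).merge(CovariateSpec(
        categorical={"exposure": (WC_LEVELS, "Stable"),
                     "base_bmi_cat": (bmi_levels, "Normal")}
    )).merge(base_spec)
    X = dmatrix(pp, spec)

    inter_cols = {}
    if interactor == "smoking_ever":
        X["ever_smoker"] = mod.to_numpy()
        targets = [dummy_name("exposure", lv) for lv in WC_LEVELS if lv != "Stable"]
        if bmi_for_interaction:
            targets += [dummy_name("base_bmi_cat", lv) for lv in bmi_levels if lv != "Normal"]
        for t in targets:
            inter_cols[f"ever_smoker:{t}"] = X[t].to_numpy() * mod.to_numpy()
    else:
        exp_targets = [dummy_name("exposure", lv) for lv in WC_LEVELS if lv != "Stable"]
        bmi_dummies = [dummy_name("base_bmi_cat", lv) for lv in bmi_levels if lv != "Normal"]
        for b in bmi_dummies:
            for t in exp_targets:
                inter_cols[f"{b}:{t}"] = X[b].to_numpy() * X[t].to_numpy()
    for name, col in inter_cols.items():
        X[name] = col

    w = None
    if weights is not None:
        w = weights.final if hasattr(weights, "final") else np.asarray(weights, dtype=float)
    res = _fit_pooled_logistic(pp["event"], X, weights=w, groups=pp["subject_id"])
    params = pd.Series(res.params, index=X.columns)
    se = pd.Series(res.bse, index=X.columns)
    tab = _hr_frame(params, se)
    inter_names = list(inter_cols)
    out = tab.loc[inter_names].copy()
    # joint Wald test over the interaction block
    cov = pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns)
    b = params[inter_names].to_numpy()
    V = cov.loc[inter_names, inter_names].to_numpy()
    stat = float(b @ np.linalg.solve(V, b))
    out.attrs["joint_wald"] = {"stat": stat, "df": len(inter_names),
                               "p": float(stats.chi2.sf(stat, len(inter_names)))}
    return out
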