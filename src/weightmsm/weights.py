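"""Stabilized inverse-probability weighting for the five-level weight-change exposure.

The denominator model is a multinomial logit of the exposure category on baseline
covariates, prior exposure and the lagged time-varying confounders; the numerator
(stabilizing) model conditions on baseline covariates and prior exposure only.  The
per-interval ratio of numerator to denominator predicted probability of the observed
category, accumulated as a running product within subject, creates the
pseudo-population in which the weight-change exposure is independent of the measured
time-varying confounders.  An analogous pair of pooled logistic models for remaining
uncensored yields optional censoring weights; because a subject censored in
(t, t+1] still contributes row t, the censoring ratio enters the product one
interval late (the current row is observed regardless of its own interval's
censoring).

Final weights are truncated at configurable percentiles (1st/99th by default) and a
denominator probability below the positivity floor raises rather than clips, so
pathological scenarios surface instead of silently distorting the fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import (EDUC_LEVELS, MARITAL_LEVELS, RACE_LEVELS, SMOKING_LEVELS,
                     WC_LEVELS)
from .design import CovariateSpec, dmatrix
from .exceptions import PositivityViolation, UnestimableModel

#: exposure codes for multinomial fitting; Stable first so it is the reference
WC_CODE = {"Stable": 0, "LargeLoss": 1, "SmallLoss": 2, "SmallGain": 3, "LargeGain": 4}
_CODE_TO_LEVEL = {v: k for k, v in WC_CODE.items()}

PRIOR_LEVELS = ("none",) + WC_LEVELS

_DEMOGRAPHICS = CovariateSpec(
    numeric=("base_age", "base_female", "base_log_income"),
    categorical={
        "base_race": (RACE_LEVELS, "white"),
        "base_educ": (EDUC_LEVELS, "highschool"),
        "base_marital": (MARITAL_LEVELS, "married"),
    },
)

_LAGGED_BLOCKS = {
    # lagged marital enters as a married indicator: the full factor is nearly
    # time-constant, so base + lagged four-level dummies separate in small samples
    "ses": CovariateSpec(numeric=("lag_log_income", "lag_married")),
    "behaviors": CovariateSpec(
        numeric=("lag_vig",),
        categorical={"lag_smoking": (SMOKING_LEVELS, "never")},
    ),
    "conditions": CovariateSpec(numeric=("lag_illness", "lag_srh_good")),
}

#: which lagged-confounder blocks enter the denominator under each model design
DESIGN_BLOCKS = {
    "M2": ("ses",),
    "M3": ("ses", "behaviors"),
    "M4": ("ses", "behaviors", "conditions"),
}


def numerator_spec() -> CovariateSpec:
    """Stabilizing model: baseline demographics + prior exposure only."""
    base = CovariateSpec(
        numeric=("base_age", "base_female"),
        categorical={
            "base_race": (RACE_LEVELS, "white"),
            "base_educ": (EDUC_LEVELS, "highschool"),
        },
    )
    return base.merge(CovariateSpec(
        categorical={"prior_exposure": (PRIOR_LEVELS, "Stable")}
    ))


def denominator_spec(design: str = "M4") -> CovariateSpec:
    if design not in DESIGN_BLOCKS:
        raise ValueError(f"design must be one of {sorted(DESIGN_BLOCKS)} (M1 is unweighted)")
    spec = numerator_spec().merge(_DEMOGRAPHICS)
    for block in DESIGN_BLOCKS[design]:
        spec = spec.merge(_LAGGED_BLOCKS[block])
    return spec


@dataclass
class FittedMultinomial:
    result: object
    spec: CovariateSpec
    converged: bool

    @property
    def coef_table(self) -> pd.DataFrame:
        cols = [_CODE_TO_LEVEL[j] for j in range(1, len(WC_CODE))]
        params = np.asarray(self.result.params)
        names = list(self.result.model.exog_names)
        return pd.DataFrame(params, index=names, columns=cols)

    @property
    def bse_table(self) -> pd.DataFrame:
        cols = [_CODE_TO_LEVEL[j] for j in range(1, len(WC_CODE))]
        return pd.DataFrame(np.asarray(self.result.bse),
                            index=list(self.result.model.exog_names), columns=cols)

    def predict_probs(self, df: pd.DataFrame) -> np.ndarray:
        """Predicted probabilities ordered as WC_LEVELS."""
        X = dmatrix(df, self.spec, strict=False)
        probs = self.result.predict(X.to_numpy())
        return probs[:, [WC_CODE[lv] for lv in WC_LEVELS]]


@dataclass
class ExposureModelPair:
    denominator: FittedMultinomial
    numerator: FittedMultinomial

    def __post_init__(self):
        if not self.numerator.spec.is_subset_of(self.denominator.spec):
            raise ValueError("numerator covariate set must nest inside the denominator's")


def _fit_multinomial(pp: pd.DataFrame, spec: CovariateSpec, cluster: bool = False):
    present = pp["exposure"].value_counts()
    empty = [lv for lv in WC_LEVELS if present.get(lv, 0) == 0]
    if empty:
        raise UnestimableModel(f"exposure level(s) with zero rows: {empty}")
    y = pp["exposure"].map(WC_CODE).to_numpy()
    X = dmatrix(pp, spec)
    model = sm.MNLogit(y, X.to_numpy())
    model.exog_names[:] = list(X.columns)
    kwargs = {}
    if cluster:
        kwargs = dict(cov_type="cluster",
                      cov_kwds={"groups": pp["subject_id"].to_numpy()})
    def _ok(res):
        params = np.asarray(res.params)
        if not np.all(np.isfinite(params)):
            return False
        # Newton's convergence flag can be false at a numerically exact optimum;
        # judge by the score norm instead
        grad = np.abs(model.score(params.ravel("F"))).max()
        return bool(res.mle_retvals.get("converged", False)) or grad < 1e-3

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(method="newton", maxiter=200, disp=0, **kwargs)
        if not _ok(res):  # Newton can diverge on near-separated draws
            res = model.fit(method="lbfgs", maxiter=2000, disp=0, **kwargs)
    if not _ok(res):
        raise UnestimableModel("multinomial exposure model did not converge")
    return res, spec


def fit_exposure_models(person_periods: pd.DataFrame, design: str = "M4",
                        denominator: CovariateSpec | None = None,
                        numerator: CovariateSpec | None = None) -> ExposureModelPair:
    """Fit the denominator (history-conditional) and numerator (stabilizing) models."""
    den_spec = denominator if denominator is not None else denominator_spec(design)
    num_spec = numerator if numerator is not None else numerator_spec()
    den_res, _ = _fit_multinomial(person_periods, den_spec)
    num_res, _ = _fit_multinomial(person_periods, num_spec)
    return ExposureModelPair(
        denominator=FittedMultinomial(den_res, den_spec, True),
        numerator=FittedMultinomial(num_res, num_spec, True),
    )


@dataclass
class CensoringModelPair:
    denominator: object
    numerator: object
    den_spec: CovariateSpec
    num_spec: CovariateSpec


def fit_censoring_models(person_periods: pd.DataFrame, design: str = "M4",
                         den_spec: CovariateSpec | None = None,
                         num_spec: CovariateSpec | None = None) -> CensoringModelPair:
    """Pooled logistic models of being censored in the interval, on the same
    covariate sets as the exposure pair."""
    den_spec = den_spec if den_spec is not None else denominator_spec(design)
    num_spec = num_spec if num_spec is not None else numerator_spec()
    y = person_periods["censor"].to_numpy(dtype=float)
    if y.sum() == 0:
        raise UnestimableModel("no censoring events; censoring weights are undefined")
    fits = []
    for spec in (den_spec, num_spec):
        X = dmatrix(person_periods, spec)
        res = sm.GLM(y, X.to_numpy(), family=sm.families.Binomial()).fit()
        fits.append(res)
    return CensoringModelPair(fits[0], fits[1], den_spec, num_spec)


@dataclass
class WeightSet:
    """Per person-period weights plus construction intermediates."""

    table: pd.DataFrame  # ratio, sw, censor_sw, weight_untruncated, weight, truncated
    truncation: tuple[float, float] | None
    bounds: tuple[float, float] | None

    @property
    def final(self) -> pd.Series:
        return self.table["weight"]


def compute_stabilized_weights(person_periods: pd.DataFrame,
                               models: ExposureModelPair,
                               censor_models: CensoringModelPair | None = None,
                               truncation: tuple[float, float] | None = (1.0, 99.0),
                               positivity_floor: float = 1e-6) -> WeightSet:
    """Stabilized weights: running product of numerator/denominator probabilities
    of the observed exposure, optionally times the analogous censoring ratio."""
    pp = person_periods
    obs = pp["exposure"].map(WC_CODE).to_numpy()
    lvl_idx = np.array([WC_CODE[lv] for lv in WC_LEVELS])
    pos = np.empty_like(obs)
    for j, code in enumerate(lvl_idx):
        pos[obs == code] = j
    p_den = models.denominator.predict_probs(pp)[np.arange(len(pp)), pos]
    p_num = models.numerator.predict_probs(pp)[np.arange(len(pp)), pos]
    low = p_den < positivity_floor
    if low.any():
        raise PositivityViolation(
            f"{int(low.sum())} person-period(s) with denominator probability below "
            f"the positivity floor {positivity_floor:g}",
            rows=pp.index[low].tolist(),
        )
    ratio = p_num / p_den

    order = pp.sort_values(["subject_id", "interval"], kind="stable").index
    r = pd.Series(ratio, index=pp.index).loc[order]
    sw = r.groupby(pp.loc[order, "subject_id"]).cumprod().reindex(pp.index)

    if censor_models is not None:
        Xd = dmatrix(pp, censor_models.den_spec).to_numpy()
        Xn = dmatrix(pp, censor_models.num_spec).to_numpy()
        unc_den = 1.0 - censor_models.denominator.predict(Xd)
        unc_num = 1.0 - censor_models.numerator.predict(Xn)
        if np.any(unc_den < positivity_floor):
            raise PositivityViolation("uncensored probability below positivity floor")
        cr = pd.Series(unc_num / unc_den, index=pp.index).loc[order]
        ccum = cr.groupby(pp.loc[order, "subject_id"]).cumprod()
        # shift one interval: a row is observed irrespective of censoring in its own interval
        csw = ccum.groupby(pp.loc[order, "subject_id"]).shift(1).fillna(1.0).reindex(pp.index)
    else:
        csw = pd.Series(1.0, index=pp.index)

    w_raw = sw * csw
    bounds = None
    if truncation is not None:
        lo_p, hi_p = truncation
        bounds = (float(np.percentile(w_raw, lo_p)), float(np.percentile(w_raw, hi_p)))
        w = w_raw.clip(*bounds)
    else:
        w = w_raw.copy()
    table = pd.DataFrame({
        "ratio": pd.Series(ratio, index=pp.index),
        "sw": sw,
        "censor_sw": csw,
        "weight_untruncated": w_raw,
        "weight": w,
        "truncated": (w != w_raw),
    })
    return WeightSet(table=table, truncation=truncation, bounds=bounds)


def weight_diagnostics(weights: WeightSet,
                       intervals: pd.Series | None = None,
                       drift_band: tuple[float, float] = (0.9, 1.1)) -> dict:
    """Summary statistics of the final weights, overall and by interval."""
    w = weights.final
    out = {
        "mean": float(w.mean()), "sd": float(w.std(ddof=0)),
        "min": float(w.min()), "max": float(w.max()),
        "p01": float(w.quantile(0.01)), "p50": float(w.quantile(0.50)),
        "p99": float(w.quantile(0.99)),
        "n_truncated": int(weights.table["truncated"].sum()),
        "sum": float(w.sum()), "n": int(len(w)),
    }
    if intervals is not None:
        by = w.groupby(intervals.to_numpy()).mean()
        out["mean_by_interval"] = {int(k): float(v) for k, v in by.items()}
        out["drift_flag"] = bool(((by < drift_band[0]) | (by > drift_band[1])).any())
    return out


def balance_diagnostics(person_periods: pd.DataFrame, weights: WeightSet,
                        confounder: str = "lag_illness") -> pd.DataFrame:
    """Weighted vs unweighted association between a lagged confounder and exposure.

    For each exposure category, regress its indicator on the confounder plus the
    stabilizing (numerator) covariates — the pseudo-population deliberately keeps
    exposure dependent on prior exposure and baseline demographics, so balance is
    assessed conditional on them — using a pooled linear probability model with
    subject-clustered robust SEs.  The weighted probe uses the interval ratio
    weight (the quantity that enforces time-t balance); under a correctly
    specified denominator its confounder z-statistics are null up to Monte-Carlo
    error, while the unweighted ones expose the raw confounding.
    """
    probe = numerator_spec()
    X = dmatrix(person_periods, probe, strict=False)
    X[confounder] = pd.to_numeric(person_periods[confounder]).to_numpy(dtype=float)
    Xn = X.to_numpy()
    j = list(X.columns).index(confounder)
    groups = person_periods["subject_id"].to_numpy()
    rows = []
    for lv in WC_LEVELS:
        y = (person_periods["exposure"] == lv).to_numpy(dtype=float)
        for label, w in (("unweighted", None),
                         ("weighted", weights.table["ratio"].to_numpy())):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.WLS(y, Xn, weights=(w if w is not None else 1.0)).fit(
                    cov_type="cluster", cov_kwds={"groups": groups})
            rows.append({"exposure": lv, "fit": label,
                         "coef": float(res.params[j]), "se": float(res.bse[j]),
                         "z": float(res.params[j] / res.bse[j])})
    return pd.DataFrame(rows)


def weighted_chi_square(person_periods: pd.DataFrame, weights: WeightSet | None,
                        confounder: str = "lag_illness") -> float:
    """Pearson chi-square of confounder x exposure, on (weighted) counts rescaled
    to the unweighted sample size.  A descriptive balance measure only."""
    w = weights.final.to_numpy() if weights is not None else np.ones(len(person_periods))
    tab = pd.crosstab(person_periods[confounder], person_periods["exposure"],
                      values=w, aggfunc="sum").fillna(0.0)
    tab = tab * len(person_periods) / tab.to_numpy().sum()
    obs = tab.to_numpy()
    expected = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
    return float(((obs - expected) ** 2 / expected).sum())
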