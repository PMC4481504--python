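"""Confounding-structure checks, the conventional comparator, and descriptive tables.

Chronic illness is a time-varying confounder with feedback if (1) health conditions
predict subsequent weight change, (2) health conditions predict mortality, and
(3) previous weight change predicts health conditions.  ``confounding_checks`` runs
these three blocks as paired model fits — each with and without baseline-covariate
adjustment — with subject-clustered robust standard errors.

``fit_naive_timedep`` is the conventional time-dependent-adjustment comparator the
weighting exists to improve on: an unweighted pooled hazard model that puts the
lagged time-varying confounders directly in the outcome model, thereby adjusting
away the part of the weight-change effect those confounders mediate.  It returns the
same result shape as the MSM for side-by-side comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohort import WC_LEVELS
from .design import CovariateSpec, dmatrix
from .exceptions import UnestimableModel
from .msm import (MSMResult, _check_events, _fit_pooled_logistic, _hr_frame,
                  _outcome_design, outcome_baseline_spec)
from .weights import _LAGGED_BLOCKS, PRIOR_LEVELS, WC_CODE, _fit_multinomial

_CODE_TO_LEVEL = {v: k for k, v in WC_CODE.items()}


@dataclass
class CheckBlock:
    outcome: str
    regressors: list
    n_rows: int
    variants: dict  # variant label -> coefficient DataFrame (est, se, z, p)
    association: bool | None  # verdict at alpha on the adjusted variant
    unestimable: str | None = None


@dataclass
class ConfounderCheckReport:
    health_to_weight_change: CheckBlock
    health_to_mortality: CheckBlock
    weight_change_to_health: CheckBlock
    alpha: float

    def blocks(self):
        return {
            "health_to_weight_change": self.health_to_weight_change,
            "health_to_mortality": self.health_to_mortality,
            "weight_change_to_health": self.weight_change_to_health,
        }


def _logit_block(pp, y, spec, alpha, health_terms):
    X = dmatrix(pp, spec)
    res = _fit_pooled_logistic(y, X, groups=pp["subject_id"])
    params = pd.Series(res.params, index=X.columns)
    se = pd.Series(res.bse, index=X.columns)
    tab = pd.DataFrame({"coef": params, "se": se, "z": params / se,
                        "p": 2 * stats.norm.sf(np.abs(params / se))})
    hit = bool((tab.loc[[t for t in health_terms if t in tab.index], "p"] < alpha).any())
    return tab, hit


def confounding_checks(person_periods: pd.DataFrame, alpha: float = 0.05) -> ConfounderCheckReport:
    """Run the three confounder-criteria blocks on a prepared person-period table."""
    pp = person_periods
    base_spec = outcome_baseline_spec("M2")  # demographic/SES adjustment set
    health = CovariateSpec(numeric=("lag_illness", "lag_srh_good"))

    # (a) health conditions -> subsequent weight change (multinomial, robust SE)
    variants_a, assoc_a, err_a = {}, None, None
    try:
        for label, spec in (
            ("unadjusted", health.merge(CovariateSpec(
                categorical={"prior_exposure": (PRIOR_LEVELS, "Stable")}))),
            ("adjusted", health.merge(base_spec).merge(CovariateSpec(
                categorical={"prior_exposure": (PRIOR_LEVELS, "Stable")}))),
        ):
            res, _ = _fit_multinomial(pp, spec, cluster=True)
            names = list(res.model.exog_names)
            cols = [_CODE_TO_LEVEL[j] for j in range(1, len(WC_CODE))]
            est = pd.DataFrame(np.asarray(res.params), index=names, columns=cols)
            se = pd.DataFrame(np.asarray(res.bse), index=names, columns=cols)
            z = est / se
            p = 2 * stats.norm.sf(np.abs(z))
            tab = pd.concat({"coef": est, "se": se, "z": z,
                             "p": pd.DataFrame(p, index=names, columns=cols)}, axis=1)
            variants_a[label] = tab
        padj = variants_a["adjusted"]["p"].loc[["lag_illness", "lag_srh_good"]]
        assoc_a = bool((padj.to_numpy() < alpha).any())
    except UnestimableModel as e:
        err_a = str(e)
    block_a = CheckBlock("exposure category", ["lag_illness", "lag_srh_good"],
                         len(pp), variants_a, assoc_a, err_a)

    # (b) health conditions -> mortality (pooled logistic); the exposure-adjusted
    # variant is emitted as well
    variants_b, assoc_b, err_b = {}, None, None
    if pp["event"].sum() == 0:
        err_b = "no deaths observed"
    else:
        for label, spec in (
            ("unadjusted", health),
            ("adjusted", health.merge(base_spec)),
            ("adjusted_plus_exposure", health.merge(base_spec).merge(
                CovariateSpec(categorical={"exposure": (WC_LEVELS, "Stable")}))),
        ):
            tab, hit = _logit_block(pp, pp["event"], spec, alpha,
                                    ["lag_illness", "lag_srh_good"])
            variants_b[label] = tab
            if label == "adjusted":
                assoc_b = hit
    block_b = CheckBlock("death in interval", ["lag_illness", "lag_srh_good"],
                         len(pp), variants_b, assoc_b, err_b)

    # (c) previous weight change -> new health conditions, among the previously
    # illness-free with a defined prior weight change
    sub = pp[(pp["lag_illness"] == 0) & (pp["prior_exposure"] != "none")]
    variants_c, assoc_c, err_c = {}, None, None
    prior_terms = [f"prior_exposure[{lv}]" for lv in WC_LEVELS if lv != "Stable"]
    if len(sub) == 0 or sub["illness_new_t"].nunique() < 2:
        err_c = "degenerate outcome: no at-risk rows or single illness level"
    else:
        prior_spec = CovariateSpec(
            categorical={"prior_exposure": (tuple(lv for lv in WC_LEVELS), "Stable")})
        for label, spec in (
            ("unadjusted", prior_spec),
            ("adjusted", prior_spec.merge(base_spec)),
        ):
            tab, hit = _logit_block(sub, sub["illness_new_t"], spec, alpha, prior_terms)
            variants_c[label] = tab
            if label == "adjusted":
                assoc_c = hit
    block_c = CheckBlock("new illness onset", prior_terms, len(sub),
                         variants_c, assoc_c, err_c)

    return ConfounderCheckReport(block_a, block_b, block_c, alpha)


_CURRENT_BLOCKS = {
    "ses": CovariateSpec(numeric=("cur_log_income", "cur_married")),
    "behaviors": CovariateSpec(
        numeric=("cur_vig",),
        categorical={"cur_smoking": (("never", "former", "current"), "never")},
    ),
    "conditions": CovariateSpec(numeric=("cur_illness", "cur_srh_good")),
}


def fit_naive_timedep(person_periods: pd.DataFrame, design: str = "M4",
                      label: str = "naive") -> MSMResult:
    """Conventional comparator: unweighted pooled hazard model with the
    time-varying confounders entered directly as covariates at their most recent
    (current interview) values.

    Conditioning on illness and self-rated health measured after the weight
    change adjusts away the part of the weight-change effect they mediate —
    the bias mechanism the weighting is built to avoid."""
    pp = person_periods
    if "weight" in pp.columns:
        warnings.warn("input carries a 'weight' column; the naive comparator is "
                      "unweighted and ignores it", stacklevel=2)
        pp = pp.drop(columns=["weight"])
    _check_events(pp)
    cur_spec = CovariateSpec()
    blocks = {"M2": ("ses",), "M3": ("ses", "behaviors"),
              "M4": ("ses", "behaviors", "conditions")}.get(design, ())
    for b in blocks:
        cur_spec = cur_spec.merge(_CURRENT_BLOCKS[b])
    extra = dmatrix(pp, cur_spec, const=False) if cur_spec.columns() else None
    X = _outcome_design(pp, design, extra=extra)
    res = _fit_pooled_logistic(pp["event"], X, groups=pp["subject_id"])
    params = pd.Series(res.params, index=X.columns)
    se = pd.Series(res.bse, index=X.columns)
    return MSMResult(
        label=label, params=params,
        cov=pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns),
        robust_se=se, hr_table=_hr_frame(params, se),
        n_subjects=int(pp["subject_id"].nunique()),
        n_person_periods=len(pp), n_events=int(pp["event"].sum()),
        weight_summary={"mean": 1.0, "all_ones": True},
    )


def _membership(panel: pd.DataFrame) -> pd.DataFrame:
    """Per subject: which weight-change categories were ever experienced."""
    from .prep import categorize_weight_change, pct_bmi_change

    panel = panel.sort_values(["subject_id", "wave"], kind="stable")
    prev = panel.groupby("subject_id")["bmi"].shift(1)
    ok = prev.notna() & panel["bmi"].notna()
    cat = pd.Series(index=panel.index, dtype=object)
    cat[ok] = np.asarray(categorize_weight_change(
        pct_bmi_change(prev[ok], panel.loc[ok, "bmi"])), dtype=object)
    member = pd.DataFrame(index=pd.Index(panel["subject_id"].unique(), name="subject_id"))
    for lv in WC_LEVELS:
        ever = panel.loc[cat == lv, "subject_id"].unique()
        member[f"ever_{lv}"] = member.index.isin(ever)
    any_change = member[[f"ever_{lv}" for lv in WC_LEVELS if lv != "Stable"]].any(axis=1)
    has_interval = panel.loc[cat.notna(), "subject_id"].unique()
    member["stable_all"] = ~any_change & member.index.isin(has_interval)
    return member


def baseline_table(panel: pd.DataFrame) -> pd.DataFrame:
    """Baseline characteristics by weight-change history, in ever-in-category
    columns (non-exclusive) plus whole-sample and stable-all-time columns."""
    from .prep import categorize_bmi

    member = _membership(panel)
    first = panel.sort_values(["subject_id", "wave"]).groupby("subject_id").first()
    first = first.loc[member.index]
    last_wave = panel.groupby("subject_id")["wave"].max().loc[member.index]
    died = panel.groupby("subject_id")["died_in_interval"].max().loc[member.index]
    followup = 2.0 * (last_wave - 1) + np.where(died == 1, 1.0, 0.0)

    groups = {"whole_sample": pd.Series(True, index=member.index)}
    for lv in ("LargeLoss", "SmallLoss"):
        groups[f"ever_{lv}"] = member[f"ever_{lv}"]
    groups["stable_all"] = member["stable_all"]
    for lv in ("SmallGain", "LargeGain"):
        groups[f"ever_{lv}"] = member[f"ever_{lv}"]

    bmi_cat = categorize_bmi(first["bmi"].where(first["bmi"] > 0))
    rows: dict[str, dict] = {}

    def put(row, col, val):
        rows.setdefault(row, {})[col] = val

    for col, mask in groups.items():
        sub = first[mask]
        put("n_subjects", col, int(mask.sum()))
        if mask.sum() == 0:
            continue
        put("female_pct", col, 100.0 * sub["female"].mean())
        put("mean_age", col, float(sub["age"].mean()))
        put("sd_age", col, float(sub["age"].std()))
        put("death_pct", col, 100.0 * died[mask].mean())
        fu = followup[mask]
        put("followup_years_died", col, float(fu[died[mask] == 1].mean()) if (died[mask] == 1).any() else np.nan)
        put("followup_years_censored", col, float(fu[died[mask] == 0].mean()) if (died[mask] == 0).any() else np.nan)
        for block, series in (
            ("race", sub["race"]), ("education", sub["education"]),
            ("marital", sub["marital_status"]), ("smoking", sub["smoking"]),
            ("baseline_bmi", bmi_cat[mask]),
        ):
            pct = series.value_counts(normalize=True) * 100.0
            for level, v in pct.items():
                put(f"{block}:{level}", col, float(v))
        put("srh_good_pct", col, 100.0 * sub["srh_good"].mean())
        put("illness_pct", col, 100.0 * sub["illness_ever"].mean())
        put("vig_activity_pct", col, 100.0 * sub["vig_activity"].mean())
        put("mean_log_income", col, float(sub["log_income"].mean()))
    return pd.DataFrame(rows).T[list(groups)]


def chi_square_independence(contingency_counts) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on an r x c count table."""
    obs = np.asarray(contingency_counts, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if np.any(obs < 0):
        raise ValueError("counts must be nonnegative")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError("all row and column margins must be positive")
    stat, p, dof, _ = stats.chi2_contingency(obs, correction=False)
    return float(stat), int(dof), float(p)


def weight_change_by_health_table(person_periods: pd.DataFrame) -> pd.DataFrame:
    """Column-percentage distribution of weight change by lagged health status,
    with the Pearson chi-square under each pair of columns."""
    out = {}
    chis = {}
    for var, labels in (("lag_illness", ("no_diagnosis", "diagnosis")),
                        ("lag_srh_good", ("poor_srh", "good_srh"))):
        counts = pd.crosstab(person_periods["exposure"], person_periods[var])
        counts = counts.reindex(index=list(WC_LEVELS)).fillna(0.0)
        stat, dof, p = chi_square_independence(counts.to_numpy())
        for j, lab in enumerate(labels):
            if j in counts.columns:
                out[lab] = 100.0 * counts[j] / counts[j].sum()
        chis[labels[1]] = (stat, p)
    tab = pd.DataFrame(out)
    tab.attrs["chi_square"] = chis
    return tab
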