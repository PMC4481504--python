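"""Panel preparation: BMI categorization, exclusion cascade, person-period expansion.

Categories follow the WHO cut-offs (18.5 / 25 / 30 / 35, each interval closed on the
left) and the five-level percentage-change classification of between-wave BMI change.
On the loss side the published interval notation overlaps at exactly -10%; here a
drop of exactly 10% is a large loss (the "≥ 10%" reading) and a drop of exactly 5% is
a small loss, keeping the five categories disjoint and exhaustive.

The exclusion cascade removes, in order: death before wave 2, dropout before wave 2,
missing BMI at any attended wave, baseline BMI > 60, and any between-consecutive-wave
BMI loss greater than 30%.  Each subject is counted once, at the first rule that
removes it, so the rule counts sum exactly to input minus retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import BMI_LEVELS, WC_LEVELS

REQUIRED_PANEL_COLUMNS = (
    "subject_id", "wave", "bmi", "died_in_interval", "censored_in_interval",
)

_BMI_EDGES = (18.5, 25.0, 30.0, 35.0)

EXCLUSION_RULES = (
    "died_before_wave2",
    "dropped_before_wave2",
    "missing_bmi_any_wave",
    "baseline_bmi_gt_60",
    "extreme_loss_gt_30pct",
)


def compute_bmi(weight_kg: float, height_m: float):
    """BMI in kg/m² from weight and height; vectorised over array inputs."""
    weight_kg = np.asarray(weight_kg, dtype=float)
    height_m = np.asarray(height_m, dtype=float)
    if np.any(weight_kg <= 0) or np.any(height_m <= 0):
        raise ValueError("weight and height must be strictly positive")
    out = weight_kg / height_m**2
    return float(out) if out.ndim == 0 else out


def categorize_bmi(bmi):
    """Map BMI to the five WHO levels; missing BMI propagates as missing."""
    arr = np.asarray(bmi, dtype=float)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    if np.any(arr[~np.isnan(arr)] <= 0):
        raise ValueError("bmi must be strictly positive")
    idx = np.digitize(arr, _BMI_EDGES)
    out = np.asarray(BMI_LEVELS, dtype=object)[idx]
    out[np.isnan(arr)] = None
    return out[0] if scalar else pd.Series(out, index=getattr(bmi, "index", None))


def pct_bmi_change(bmi_prev, bmi_curr):
    """Percentage BMI change between two consecutive interviews."""
    prev = np.asarray(bmi_prev, dtype=float)
    curr = np.asarray(bmi_curr, dtype=float)
    if np.any(prev[~np.isnan(prev)] <= 0) or np.any(curr[~np.isnan(curr)] <= 0):
        raise ValueError("BMI values must be strictly positive")
    out = 100.0 * (curr - prev) / prev
    return float(out) if out.ndim == 0 else out


def categorize_weight_change(p):
    """Five-level weight-change category for a percentage BMI change.

    Large loss p <= -10; small loss -10 < p <= -5; stable -5 < p < 5;
    small gain 5 <= p < 10; large gain p >= 10.
    """
    arr = np.asarray(p, dtype=float)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    out = np.empty(arr.shape, dtype=object)
    out[arr <= -10.0] = "LargeLoss"
    out[(arr > -10.0) & (arr <= -5.0)] = "SmallLoss"
    out[(arr > -5.0) & (arr < 5.0)] = "Stable"
    out[(arr >= 5.0) & (arr < 10.0)] = "SmallGain"
    out[arr >= 10.0] = "LargeGain"
    out[np.isnan(arr)] = None
    return out[0] if scalar else pd.Series(out, index=getattr(p, "index", None))


@dataclass
class ExclusionReport:
    """Subject-level accounting of the exclusion cascade.

    ``n_retained_subjects`` is always input minus the per-rule counts; when built
    from printed totals rather than data it reproduces the published arithmetic.
    """

    n_input_subjects: int
    counts: dict = field(default_factory=dict)
    n_person_periods: int | None = None
    n_retained_subjects: int = field(init=False)

    def __post_init__(self):
        for rule in EXCLUSION_RULES:
            self.counts.setdefault(rule, 0)
        self.n_retained_subjects = self.n_input_subjects - sum(self.counts.values())

    def as_dict(self) -> dict:
        out = {"n_input_subjects": self.n_input_subjects}
        out.update(self.counts)
        out["n_retained_subjects"] = self.n_retained_subjects
        if self.n_person_periods is not None:
            out["n_person_periods"] = self.n_person_periods
        return out

    def write(self, path) -> None:
        with open(path, "w") as fh:
            for k, v in self.as_dict().items():
                fh.write(f"{k}\t{v}\n")


def _check_columns(panel: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_PANEL_COLUMNS if c not in panel.columns]
    if missing:
        raise ValueError(f"panel is missing required columns: {missing}")


def apply_exclusions(panel: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionReport]:
    """Apply the exclusion cascade; subjects counted once at their first matching rule."""
    _check_columns(panel)
    counts = {rule: 0 for rule in EXCLUSION_RULES}
    n_input = panel["subject_id"].nunique()
    if len(panel) == 0:
        return panel.copy(), ExclusionReport(0, counts, n_person_periods=0)

    panel_sorted = panel.sort_values(["subject_id", "wave"], kind="stable")
    sid = panel_sorted["subject_id"]
    ids = pd.Index(sid.unique())

    w1 = panel_sorted[panel_sorted["wave"] == 1]
    died_w1 = pd.Series(False, index=ids)
    died_w1.loc[w1.loc[w1["died_in_interval"] == 1, "subject_id"]] = True
    has_w2 = pd.Series(False, index=ids)
    has_w2.loc[panel_sorted.loc[panel_sorted["wave"] == 2, "subject_id"].unique()] = True
    dropped_w1 = ~died_w1 & ~has_w2
    missing_bmi = panel_sorted["bmi"].isna().groupby(sid).any().reindex(ids, fill_value=False)
    base_gt60 = pd.Series(False, index=ids)
    base_gt60.loc[w1.loc[w1["bmi"] > 60.0, "subject_id"]] = True

    bmi_prev = panel_sorted.groupby("subject_id")["bmi"].shift(1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = 100.0 * (panel_sorted["bmi"] - bmi_prev) / bmi_prev
    extreme = (pct < -30.0).groupby(sid).any().reindex(ids, fill_value=False)

    rules = [
        ("died_before_wave2", died_w1),
        ("dropped_before_wave2", dropped_w1),
        ("missing_bmi_any_wave", missing_bmi),
        ("baseline_bmi_gt_60", base_gt60),
        ("extreme_loss_gt_30pct", extreme),
    ]
    removed = pd.Series(False, index=ids)
    for name, mask in rules:
        hit = mask & ~removed
        counts[name] = int(hit.sum())
        removed |= mask.astype(bool)

    keep_ids = removed.index[~removed]
    out = panel[panel["subject_id"].isin(keep_ids)].copy()
    report = ExclusionReport(
        n_input, counts,
        n_person_periods=int(len(out) - out["subject_id"].nunique()),
    )
    return out, report


BASELINE_RENAME = {
    "age": "base_age", "female": "base_female", "race": "base_race",
    "education": "base_educ", "marital_status": "base_marital",
    "log_income": "base_log_income", "smoking": "base_smoking",
    "srh_good": "base_srh_good", "illness_ever": "base_illness",
    "vig_activity": "base_vig",
}
LAG_RENAME = {
    "illness_ever": "lag_illness", "srh_good": "lag_srh_good",
    "smoking": "lag_smoking", "vig_activity": "lag_vig",
    "marital_status": "lag_marital", "log_income": "lag_log_income",
}
# current-wave (interview t) values: used only by the conventional comparator,
# which conditions on confounders measured after the weight change
CURRENT_RENAME = {
    "illness_ever": "cur_illness", "srh_good": "cur_srh_good",
    "smoking": "cur_smoking", "vig_activity": "cur_vig",
    "log_income": "cur_log_income",
}


def build_person_periods(panel: pd.DataFrame) -> pd.DataFrame:
    """Expand an exclusion-filtered panel into one row per subject-interval.

    Interval ``t`` runs from wave ``t`` to ``t+1`` and carries: the exposure
    realized between waves ``t-1`` and ``t``; every time-varying covariate at its
    wave ``t-1`` (lagged) value; baseline covariates from wave 1; and the death /
    censoring indicator for the interval.  A subject attending waves 1..K and never
    missing an interview contributes K-1 rows; a missed interview truncates
    follow-up at the last attended pre-gap wave (treated as dropout there).
    """
    _check_columns(panel)
    panel = panel.sort_values(["subject_id", "wave"], kind="stable").copy()
    if (panel.groupby("subject_id")["wave"].diff().dropna() <= 0).any():
        raise ValueError("wave indices must be strictly increasing within subject")

    # truncate at the first missed interview: gaps count as dropout
    gap = panel.groupby("subject_id")["wave"].diff().gt(1)
    first_gap = panel.loc[gap].groupby("subject_id")["wave"].min()
    if len(first_gap):
        cut = panel["subject_id"].map(first_gap)
        keep = cut.isna() | (panel["wave"] < cut)
        panel = panel[keep].copy()
        last = panel.groupby("subject_id")["wave"].transform("max")
        truncated = panel["subject_id"].isin(first_gap.index) & panel["wave"].eq(last)
        panel.loc[truncated & panel["died_in_interval"].eq(0), "censored_in_interval"] = 1

    grp = panel.groupby("subject_id", sort=False)
    base = panel.loc[grp["wave"].idxmin()].set_index("subject_id")
    if (base["wave"] != 1).any():
        raise ValueError("every subject must have a wave-1 record")

    pp = panel.copy()
    pp["bmi_prev"] = grp["bmi"].shift(1)
    for raw, lagged in LAG_RENAME.items():
        pp[lagged] = grp[raw].shift(1)
    for raw, cur in CURRENT_RENAME.items():
        pp[cur] = pp[raw]
    pp["cur_married"] = (pp["marital_status"] == "married").astype(int)
    pp = pp[pp["wave"] >= 2].copy()
    pp["pct_change"] = pct_bmi_change(pp["bmi_prev"], pp["bmi"])
    pp["exposure"] = categorize_weight_change(pp["pct_change"])
    pp["prior_exposure"] = (
        pp.groupby("subject_id")["exposure"].shift(1).fillna("none")
    )
    if pp["exposure"].isna().any():
        raise ValueError("exposure missing on retained person-periods; "
                         "apply_exclusions must run first")
    if "lag_marital" in pp.columns:
        pp["lag_married"] = (pp["lag_marital"] == "married").astype(int)

    base_cols = {raw: name for raw, name in BASELINE_RENAME.items() if raw in base.columns}
    base_df = base[list(base_cols)].rename(columns=base_cols)
    base_df["base_bmi_cat"] = categorize_bmi(base["bmi"])
    pp = pp.merge(base_df, left_on="subject_id", right_index=True, how="left")

    pp = pp.rename(columns={"wave": "interval", "died_in_interval": "event",
                            "censored_in_interval": "censor",
                            "illness_new": "illness_new_t"})
    cols = (
        ["subject_id", "interval", "exposure", "prior_exposure", "pct_change",
         "event", "censor", "base_bmi_cat", "illness_new_t"]
        + list(BASELINE_RENAME.values()) + list(LAG_RENAME.values())
        + ["lag_married"] + list(CURRENT_RENAME.values()) + ["cur_married"]
    )
    cols = [c for c in cols if c in pp.columns]
    return pp[cols].reset_index(drop=True)


def prepare(panel: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionReport]:
    """Exclusion cascade followed by person-period expansion."""
    filtered, report = apply_exclusions(panel)
    return build_person_periods(filtered), report
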