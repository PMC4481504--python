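"""Synthetic biennial cohort generator with treatment–confounder feedback.

The generator emulates the structure of a longitudinal ageing survey: subjects enter
at ages 50–60, are interviewed every two years for up to ``n_waves`` waves, and report
BMI, chronic-disease diagnoses, self-rated health, smoking, physical activity,
marital status and household income at each wave.  Between consecutive waves the
subject's BMI moves by a percentage drawn within one of five weight-change categories
(large loss <= -10%, small loss (-10,-5], stable (-5,5), small gain [5,10), large
gain >= 10%), with the within-category percentage uniform inside the category bounds
(loss capped at 30% so generated data stay inside the analysed support).

The causal structure is the one that makes chronic illness a time-varying confounder
with feedback:

* weight status and past weight change raise the probability of illness onset;
* illness (and poor self-rated health, and smoking) raises the probability of
  subsequent weight loss;
* illness, poor self-rated health and smoking independently raise mortality.

All binary transitions are logistic and the exposure assignment is multinomial
logistic, so the analysis-side denominator model is correctly specifiable and
weighting correctness can be isolated from model misspecification.  Death in the
interval (t, t+1] is drawn after the wave-t weight change is realized, so current
exposure affects current-interval mortality; dropout depends on lagged (previous
wave) health only, so censoring models conditioning on observed history are
correctly specified as well.

``oracle_marginal_effects`` provides the ground truth for recovery tests: it refits
the stabilizing (numerator) exposure distribution on a large confounded draw, then
re-simulates the same world with exposure assigned from that distribution — i.e. with
the confounder arrows into exposure cut — and fits the marginal pooled hazard model
there.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .exceptions import UnestimableModel

WC_LEVELS = ("LargeLoss", "SmallLoss", "Stable", "SmallGain", "LargeGain")
#: within-category bounds (percent BMI change) used for the uniform draw
WC_BOUNDS = {
    "LargeLoss": (-30.0, -10.0),
    "SmallLoss": (-10.0, -5.0),
    "Stable": (-5.0, 5.0),
    "SmallGain": (5.0, 10.0),
    "LargeGain": (10.0, 30.0),
}
BMI_LEVELS = ("Underweight", "Normal", "Overweight", "ObeseI", "ObeseII_III")
SMOKING_LEVELS = ("never", "former", "current")
RACE_LEVELS = ("white", "black", "hispanic", "other")
EDUC_LEVELS = ("lt_highschool", "highschool", "some_college", "college")
MARITAL_LEVELS = ("married", "never_married", "divorced_separated", "widowed")

PRESETS = ("confounded", "null_effect", "no_feedback", "strong_reverse_causality")

_INCOME_CENTER = 10.8  # log household income centering used by the dropout model


@dataclass
class ScenarioParams:
    """Full generative parameter set for one synthetic-cohort scenario.

    ``exposure_coefs``, ``illness_coefs``, ``srh_coefs``, ``structural_mortality``
    and ``dropout_coefs`` are plain nested dicts of named log-odds terms so that a
    scenario is serialisable as a flat config and auditable at a glance.  Reference
    categories (Stable exposure, Normal baseline BMI) carry explicit zero entries.
    """

    n_subjects: int = 3000
    n_waves: int = 10
    seed: int = 0
    baseline_age_range: tuple[float, float] = (50.0, 60.0)
    baseline_bmi_mixture: dict = field(default_factory=dict)
    demographics: dict = field(default_factory=dict)
    baseline_health: dict = field(default_factory=dict)
    exposure_coefs: dict = field(default_factory=dict)
    illness_coefs: dict = field(default_factory=dict)
    srh_coefs: dict = field(default_factory=dict)
    smoking_transition: dict = field(default_factory=dict)
    structural_mortality: dict = field(default_factory=dict)
    dropout_coefs: dict = field(default_factory=dict)
    income_wealth_model: dict = field(default_factory=dict)
    p_missing_bmi: float = 0.012

    def validate(self) -> None:
        if self.n_waves < 3:
            raise ValueError(
                "n_waves must be >= 3: the exposure needs two consecutive BMI "
                "measures and the outcome a subsequent interval"
            )
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        lo, hi = self.baseline_age_range
        if not lo < hi:
            raise ValueError("baseline_age_range must be an increasing pair")
        w = np.asarray(self.baseline_bmi_mixture["weights"], dtype=float)
        if not np.isclose(w.sum(), 1.0):
            raise ValueError("baseline BMI mixture weights must sum to 1")
        if self.structural_mortality["exposure"]["Stable"] != 0.0:
            raise ValueError("reference exposure (Stable) log-HR must be exactly 0")
        if self.structural_mortality["bmi"]["Normal"] != 0.0:
            raise ValueError("reference baseline-BMI (Normal) log-HR must be exactly 0")
        for row in self.smoking_transition.values():
            if not np.isclose(sum(row.values()), 1.0):
                raise ValueError("smoking transition rows must sum to 1")

    def copy(self) -> "ScenarioParams":
        return copy.deepcopy(self)


def _confounded_params() -> ScenarioParams:
    exposure = {
        "LargeLoss": dict(
            const=-3.05, age55=0.030, female=0.10, lag_illness=0.85,
            lag_poor_srh=0.60, lag_smoke_current=0.30, lag_smoke_former=0.05,
            lag_vig=-0.10,
            prior={"LargeLoss": 2.00, "SmallLoss": 1.00, "Stable": 0.0,
                   "SmallGain": 0.10, "LargeGain": 0.50},
        ),
        "SmallLoss": dict(
            const=-1.95, age55=0.015, female=0.05, lag_illness=0.35,
            lag_poor_srh=0.25, lag_smoke_current=0.10, lag_smoke_former=0.00,
            lag_vig=-0.05,
            prior={"LargeLoss": 1.00, "SmallLoss": 1.50, "Stable": 0.0,
                   "SmallGain": 0.15, "LargeGain": 0.25},
        ),
        "SmallGain": dict(
            const=-1.75, age55=-0.010, female=0.05, lag_illness=0.05,
            lag_poor_srh=0.05, lag_smoke_current=-0.05, lag_smoke_former=0.10,
            lag_vig=-0.05,
            prior={"LargeLoss": 0.15, "SmallLoss": 0.10, "Stable": 0.0,
                   "SmallGain": 0.30, "LargeGain": 0.25},
        ),
        "LargeGain": dict(
            const=-2.75, age55=-0.020, female=0.20, lag_illness=0.35,
            lag_poor_srh=0.45, lag_smoke_current=0.20, lag_smoke_former=0.15,
            lag_vig=-0.10,
            prior={"LargeLoss": 0.50, "SmallLoss": 0.15, "Stable": 0.0,
                   "SmallGain": 0.25, "LargeGain": 0.60},
        ),
    }
    return ScenarioParams(
        baseline_bmi_mixture=dict(
            weights=[0.44, 0.40, 0.16], means=[23.3, 28.0, 33.5],
            sds=[2.2, 2.2, 4.5], lower=14.5, upper=70.0,
        ),
        demographics=dict(
            p_female=0.51,
            race_probs=[0.754, 0.151, 0.074, 0.021],
            educ_probs=[0.223, 0.375, 0.202, 0.200],
            marital_probs=[0.749, 0.040, 0.151, 0.060],
            smoking_probs=[0.368, 0.367, 0.265],
        ),
        baseline_health=dict(
            illness=dict(const=-1.15, age=0.03,
                         bmi={"Underweight": 0.30, "Normal": 0.0, "Overweight": 0.10,
                              "ObeseI": 0.30, "ObeseII_III": 0.60},
                         smoke_current=0.40, smoke_former=0.20),
            srh=dict(const=1.90, illness=-1.50),
            vig=dict(const=-0.95, illness=-0.50, age=-0.02),
        ),
        exposure_coefs=exposure,
        illness_coefs=dict(
            const=-2.70, age=0.04,
            bmi={"Underweight": 0.30, "Normal": 0.0, "Overweight": 0.15,
                 "ObeseI": 0.40, "ObeseII_III": 0.70},
            prior_wc={"LargeLoss": 2.00, "SmallLoss": 1.50, "Stable": 0.0,
                      "SmallGain": 0.10, "LargeGain": 0.80},
            smoke_current=0.50, smoke_former=0.20,
        ),
        srh_coefs=dict(
            const=1.80, illness=-1.50,
            prior_wc={"LargeLoss": -1.50, "SmallLoss": -1.00, "Stable": 0.0,
                      "SmallGain": -0.05, "LargeGain": -0.70},
        ),
        smoking_transition={
            "never": {"never": 0.995, "former": 0.0, "current": 0.005},
            "former": {"never": 0.0, "former": 0.97, "current": 0.03},
            "current": {"never": 0.0, "former": 0.06, "current": 0.94},
        },
        structural_mortality=dict(
            const=-5.05, age_slope=0.07,
            exposure={"LargeLoss": 0.79, "SmallLoss": 0.34, "Stable": 0.0,
                      "SmallGain": 0.14, "LargeGain": 0.47},
            bmi={"Underweight": 0.59, "Normal": 0.0, "Overweight": -0.05,
                 "ObeseI": 0.10, "ObeseII_III": 0.47},
            illness=0.90, poor_srh=0.70,
            smoke_current=0.53, smoke_former=0.18,
        ),
        dropout_coefs=dict(const=-3.35, lag_illness=0.25, lag_poor_srh=0.40,
                           log_income=-0.05),
        income_wealth_model=dict(mean=_INCOME_CENTER, sd=0.70, walk_sd=0.12,
                                 educ_shift=[-0.5, 0.0, 0.3, 0.6]),
    )


def default_params(preset: str, n_subjects: int | None = None,
                   n_waves: int | None = None, seed: int | None = None) -> ScenarioParams:
    """Return a fully specified :class:`ScenarioParams` for a named preset.

    * ``confounded`` — illness→weight-loss and weight→illness feedback with
      nonzero structural mortality effects ordered large loss > large gain >
      small loss > small gain > stable.
    * ``null_effect`` — all structural exposure and baseline-BMI log-HRs set to
      0 and the mediated pathway (weight change → illness/self-rated health)
      cut, so the total effect of exposure is truly null while confounding by
      illness persists.
    * ``no_feedback`` — illness onset no longer depends on prior weight change.
    * ``strong_reverse_causality`` — illness→large-loss and illness→death
      coefficients inflated.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; valid presets: {list(PRESETS)}")
    params = _confounded_params()
    if preset == "null_effect":
        params.structural_mortality["exposure"] = {lv: 0.0 for lv in WC_LEVELS}
        params.structural_mortality["bmi"] = {lv: 0.0 for lv in BMI_LEVELS}
        # a truly null total effect also requires cutting every mediated pathway:
        # weight change -> illness / self-rated health -> death, and weight
        # change -> attained BMI level -> illness onset -> death; confounding by
        # illness remains through its effects on exposure and mortality
        params.illness_coefs["prior_wc"] = {lv: 0.0 for lv in WC_LEVELS}
        params.srh_coefs["prior_wc"] = {lv: 0.0 for lv in WC_LEVELS}
        params.illness_coefs["bmi"] = {lv: 0.0 for lv in BMI_LEVELS}
    elif preset == "no_feedback":
        params.illness_coefs["prior_wc"] = {lv: 0.0 for lv in WC_LEVELS}
    elif preset == "strong_reverse_causality":
        params.exposure_coefs["LargeLoss"]["lag_illness"] = 1.50
        params.structural_mortality["illness"] = 1.25
    if n_subjects is not None:
        params.n_subjects = n_subjects
    if n_waves is not None:
        params.n_waves = n_waves
    if seed is not None:
        params.seed = seed
    params.validate()
    return params


def _bmi_category_idx(bmi: np.ndarray) -> np.ndarray:
    """Indices into BMI_LEVELS for an array of BMI values."""
    return np.digitize(bmi, [18.5, 25.0, 30.0, 35.0])


def _pick(prob_rows: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw one category per row from a matrix of row-stochastic probabilities."""
    u = rng.random((prob_rows.shape[0], 1))
    return (prob_rows.cumsum(axis=1) > u).argmax(axis=1)


def _finite(logit: np.ndarray) -> np.ndarray:
    if not np.all(np.isfinite(logit)):
        raise ValueError("non-finite logit produced by scenario coefficients")
    return logit


def simulate_cohort(params: ScenarioParams, include_latent: bool = False,
                    _exposure_override=None, _disable_dropout: bool = False,
                    _disable_missing: bool = False) -> pd.DataFrame:
    """Simulate a long-format person-wave panel; deterministic given ``params.seed``.

    One row per attended wave per subject; no rows after death or dropout.
    ``died_in_interval`` / ``censored_in_interval`` describe the two-year interval
    following the row's wave.  With ``include_latent`` the drawn weight-change
    category and percentage are attached as ``_wc_cat`` / ``_pct_change`` (the
    observable route recovers them from the recorded BMI values).

    The private hooks swap the exposure-assignment mechanism and switch off
    dropout/missingness; :func:`oracle_marginal_effects` uses them to build the
    unconfounded intervention world.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_subjects
    dem = params.demographics
    mix = params.baseline_bmi_mixture
    bh = params.baseline_health
    inc = params.income_wealth_model
    mort = params.structural_mortality

    female = (rng.random(n) < dem["p_female"]).astype(np.int8)
    age = rng.uniform(*params.baseline_age_range, n)
    race = rng.choice(len(RACE_LEVELS), n, p=dem["race_probs"])
    educ = rng.choice(len(EDUC_LEVELS), n, p=dem["educ_probs"])
    marital = rng.choice(len(MARITAL_LEVELS), n, p=dem["marital_probs"])
    smoking = rng.choice(3, n, p=dem["smoking_probs"])

    comp = rng.choice(len(mix["weights"]), n, p=mix["weights"])
    bmi = rng.normal(np.asarray(mix["means"])[comp], np.asarray(mix["sds"])[comp])
    bmi = np.clip(bmi, mix["lower"], mix["upper"])
    base_bmi_idx = _bmi_category_idx(bmi)

    ic = bh["illness"]
    p_ill = expit(_finite(
        ic["const"] + ic["age"] * (age - 55.0)
        + np.array([ic["bmi"][lv] for lv in BMI_LEVELS])[base_bmi_idx]
        + ic["smoke_current"] * (smoking == 2) + ic["smoke_former"] * (smoking == 1)
    ))
    illness = (rng.random(n) < p_ill).astype(np.int8)
    srh_good = (rng.random(n) < expit(bh["srh"]["const"] + bh["srh"]["illness"] * illness)).astype(np.int8)
    vc = bh["vig"]
    vig = (rng.random(n) < expit(vc["const"] + vc["illness"] * illness + vc["age"] * (age - 55.0))).astype(np.int8)
    log_income = rng.normal(inc["mean"] + np.asarray(inc["educ_shift"])[educ], inc["sd"])

    exposure = np.full(n, -1, dtype=np.int64)  # -1: no weight change defined yet
    active = np.ones(n, dtype=bool)
    subject_id = np.arange(1, n + 1)

    trans = np.array(
        [[params.smoking_transition[a][b] for b in SMOKING_LEVELS] for a in SMOKING_LEVELS]
    )

    rows: list[pd.DataFrame] = []
    illness_new = illness.copy()  # first interview reports "ever" status

    for t in range(1, params.n_waves + 1):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        if t > 1:
            # snapshot wave t-1 state: exposure at wave t depends on lagged values only
            lag_ill = illness[idx].copy()
            lag_srh = srh_good[idx].copy()
            lag_smoke = smoking[idx].copy()
            lag_vig = vig[idx].copy()
            prior_exp = exposure[idx].copy()

            smoking[idx] = _pick(trans[smoking[idx]], rng)
            log_income[idx] = log_income[idx] + rng.normal(0.0, inc["walk_sd"], idx.size)
            # rare marital transitions: widowhood/divorce among the married,
            # (re)marriage among the unmarried
            married = idx[marital[idx] == 0]
            u = rng.random(married.size)
            marital[married[u < 0.012]] = 3
            marital[married[(u >= 0.012) & (u < 0.020)]] = 2
            unmarried = idx[marital[idx] != 0]
            marital[unmarried[rng.random(unmarried.size) < 0.02]] = 0

            il = params.illness_coefs
            prev_bmi_idx = _bmi_category_idx(bmi[idx])
            prior_wc_vec = np.zeros(idx.size)
            has_prior = prior_exp >= 0
            prior_wc_arr = np.array([il["prior_wc"][lv] for lv in WC_LEVELS])
            prior_wc_vec[has_prior] = prior_wc_arr[prior_exp[has_prior]]
            p_onset = expit(_finite(
                il["const"] + il["age"] * (age[idx] - 55.0)
                + np.array([il["bmi"][lv] for lv in BMI_LEVELS])[prev_bmi_idx]
                + prior_wc_vec
                + il["smoke_current"] * (smoking[idx] == 2)
                + il["smoke_former"] * (smoking[idx] == 1)
            ))
            onset = (illness[idx] == 0) & (rng.random(idx.size) < p_onset)
            illness_new = np.zeros(n, dtype=np.int8)
            illness_new[idx[onset]] = 1
            illness[idx[onset]] = 1

            sc = params.srh_coefs
            srh_wc = np.zeros(idx.size)
            srh_arr = np.array([sc["prior_wc"][lv] for lv in WC_LEVELS])
            srh_wc[has_prior] = srh_arr[prior_exp[has_prior]]
            srh_good[idx] = (rng.random(idx.size) < expit(
                sc["const"] + sc["illness"] * illness[idx] + srh_wc)).astype(np.int8)

            vig[idx] = (rng.random(idx.size) < expit(
                vc["const"] + 1.2 * lag_vig + vc["illness"] * illness[idx]
                + vc["age"] * (age[idx] - 55.0))).astype(np.int8)

            if _exposure_override is not None:
                probs = _exposure_override(
                    subject_id=subject_id[idx], female=female[idx], age0=age[idx] - 2.0 * (t - 1),
                    race=race[idx], educ=educ[idx], marital0=None,
                    prior_exposure=prior_exp, t=t,
                )
            else:
                logits = np.zeros((idx.size, len(WC_LEVELS)))
                for j, lv in enumerate(WC_LEVELS):
                    if lv == "Stable":
                        continue
                    cf = params.exposure_coefs[lv]
                    prior_vec = np.zeros(idx.size)
                    prior_arr = np.array([cf["prior"][p] for p in WC_LEVELS])
                    prior_vec[has_prior] = prior_arr[prior_exp[has_prior]]
                    logits[:, j] = _finite(
                        cf["const"]
                        + cf["age55"] * (age[idx] - 2.0 * (t - 1) - 55.0)  # entry age
                        + cf["female"] * female[idx]
                        + cf["lag_illness"] * lag_ill
                        + cf["lag_poor_srh"] * (1 - lag_srh)
                        + cf["lag_smoke_current"] * (lag_smoke == 2)
                        + cf["lag_smoke_former"] * (lag_smoke == 1)
                        + cf["lag_vig"] * lag_vig
                        + prior_vec
                    )
                logits -= logits.max(axis=1, keepdims=True)
                probs = np.exp(logits)
                probs /= probs.sum(axis=1, keepdims=True)
            new_exp = _pick(probs, rng)
            lo = np.array([WC_BOUNDS[lv][0] for lv in WC_LEVELS])[new_exp]
            hi = np.array([WC_BOUNDS[lv][1] for lv in WC_LEVELS])[new_exp]
            pct = rng.uniform(lo, hi)
            bmi[idx] = bmi[idx] * (1.0 + pct / 100.0)
            exposure[idx] = new_exp
        else:
            lag_ill, lag_srh = illness[idx], srh_good[idx]
            pct = np.zeros(idx.size)

        bmi_obs = bmi[idx].copy()
        if params.p_missing_bmi > 0 and not _disable_missing:
            bmi_obs[rng.random(idx.size) < params.p_missing_bmi] = np.nan

        # death in (t, t+1]: drawn after the wave-t exposure is realized
        exp_term = np.zeros(idx.size)
        cur = exposure[idx]
        exp_arr = np.array([mort["exposure"][lv] for lv in WC_LEVELS])
        exp_term[cur >= 0] = exp_arr[cur[cur >= 0]]
        p_death = expit(_finite(
            mort["const"] + mort["age_slope"] * (age[idx] - 55.0)
            + exp_term
            + np.array([mort["bmi"][lv] for lv in BMI_LEVELS])[base_bmi_idx[idx]]
            + mort["illness"] * illness[idx]
            + mort["poor_srh"] * (1 - srh_good[idx])
            + mort["smoke_current"] * (smoking[idx] == 2)
            + mort["smoke_former"] * (smoking[idx] == 1)
        ))
        died = rng.random(idx.size) < p_death
        if _disable_dropout:
            censored = np.zeros(idx.size, dtype=bool)
        else:
            dc = params.dropout_coefs
            p_drop = expit(_finite(
                dc["const"] + dc["lag_illness"] * lag_ill
                + dc["lag_poor_srh"] * (1 - lag_srh)
                + dc["log_income"] * (log_income[idx] - _INCOME_CENTER)
            ))
            censored = (~died) & (rng.random(idx.size) < p_drop)

        row = {
            "subject_id": subject_id[idx],
            "wave": np.full(idx.size, t),
            "age": age[idx],
            "female": female[idx],
            "race": np.asarray(RACE_LEVELS, dtype=object)[race[idx]],
            "education": np.asarray(EDUC_LEVELS, dtype=object)[educ[idx]],
            "marital_status": np.asarray(MARITAL_LEVELS, dtype=object)[marital[idx]],
            "log_income": log_income[idx],
            "bmi": bmi_obs,
            "illness_ever": illness[idx].astype(np.int8),
            "illness_new": illness_new[idx].astype(np.int8),
            "srh_good": srh_good[idx],
            "smoking": np.asarray(SMOKING_LEVELS, dtype=object)[smoking[idx]],
            "vig_activity": vig[idx],
            "alive_at_wave": np.ones(idx.size, dtype=np.int8),
            "died_in_interval": died.astype(np.int8),
            "censored_in_interval": censored.astype(np.int8),
        }
        if include_latent:
            row["_bmi_latent"] = bmi[idx].copy()
            row["_pct_change"] = pct if t > 1 else np.full(idx.size, np.nan)
            row["_wc_cat"] = (
                np.asarray(WC_LEVELS, dtype=object)[exposure[idx]]
                if t > 1 else np.full(idx.size, None, dtype=object)
            )
        rows.append(pd.DataFrame(row))

        active[idx[died | censored]] = False
        age += 2.0

    panel = pd.concat(rows, ignore_index=True)
    return panel.sort_values(["subject_id", "wave"], kind="stable").reset_index(drop=True)


@dataclass
class OracleResult:
    """Marginal (pseudo-population scale) truth from the intervention world."""

    log_hr: pd.Series
    se: pd.Series
    n_subjects: int
    n_person_periods: int
    n_events: int


def oracle_marginal_effects(params: ScenarioParams, n_oracle: int = 500_000,
                            seed: int | None = None,
                            numerator_n: int | None = None) -> OracleResult:
    """True marginal log-HRs for the 8 exposure/baseline-BMI parameters.

    The stabilizing exposure distribution (baseline covariates + prior exposure) is
    fit on a large confounded draw from ``params``; the cohort is then re-simulated
    with exposure assigned from that fitted distribution and no dropout, which cuts
    every confounder arrow into exposure while leaving illness dynamics, mediation
    and mortality untouched.  The pooled discrete-time hazard model fit to this
    randomized world is the estimand the weighted analysis targets.
    """
    from . import msm, prep, weights  # deferred: avoids an import cycle

    if seed is None:
        seed = params.seed
    rng = np.random.default_rng(seed)
    s_fit, s_int = (int(x) for x in rng.integers(0, 2**31 - 1, 2))
    if numerator_n is None:
        numerator_n = min(n_oracle, 100_000)

    fit_params = replace(copy.deepcopy(params), n_subjects=numerator_n, seed=s_fit)
    panel = simulate_cohort(fit_params)
    pp = prep.build_person_periods(prep.apply_exclusions(panel)[0])
    num_res, num_spec = weights._fit_multinomial(pp, weights.numerator_spec())

    def assign(subject_id, female, age0, race, educ, marital0, prior_exposure, t):
        df = pd.DataFrame({
            "base_age": age0,
            "base_female": female,
            "base_race": np.asarray(RACE_LEVELS, dtype=object)[race],
            "base_educ": np.asarray(EDUC_LEVELS, dtype=object)[educ],
            "prior_exposure": np.where(
                prior_exposure >= 0,
                np.asarray(WC_LEVELS, dtype=object)[np.clip(prior_exposure, 0, None)],
                "none",
            ),
        })
        from .design import dmatrix

        X = dmatrix(df, num_spec, strict=False)
        probs = num_res.predict(X.to_numpy())
        # model categories are coded Stable-first; reorder to WC_LEVELS
        return probs[:, [weights.WC_CODE[lv] for lv in WC_LEVELS]]

    int_params = replace(copy.deepcopy(params), n_subjects=n_oracle, seed=s_int)
    world = simulate_cohort(int_params, _exposure_override=assign,
                            _disable_dropout=True, _disable_missing=True)
    pp_int = prep.build_person_periods(prep.apply_exclusions(world)[0])
    # keep only the outcome-model columns: the intervention world is large and
    # the lagged/current covariate blocks are not used by the marginal fit
    keep_cols = [c for c in pp_int.columns
                 if c in ("subject_id", "interval", "exposure", "event", "censor")
                 or c.startswith("base_")]
    pp_int = pp_int[keep_cols]
    del world
    import gc

    gc.collect()
    ev = pp_int.groupby("exposure", observed=True)["event"].sum()
    empty = [lv for lv in WC_LEVELS if ev.get(lv, 0) == 0]
    if empty:
        raise UnestimableModel(
            f"n_oracle={n_oracle} too small: zero events in exposure categories {empty}"
        )
    result = msm.fit_msm(pp_int, weights=None, design="M4", cluster_robust=False)
    keep = [c for c in result.params.index
            if c.startswith("exposure[") or c.startswith("base_bmi_cat[")]
    return OracleResult(
        log_hr=result.params[keep],
        se=result.robust_se[keep],
        n_subjects=int(pp_int["subject_id"].nunique()),
        n_person_periods=len(pp_int),
        n_events=int(pp_int["event"].sum()),
    )


def write_panel(panel: pd.DataFrame, path) -> None:
    """Write the long-format panel as delimited text (empty fields for missing)."""
    panel.to_csv(path, index=False)


def read_panel(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_params(params: ScenarioParams, path) -> None:
    """Write ScenarioParams as a flat YAML config so a run is reproducible."""
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump(
            {k: getattr(params, k) for k in params.__dataclass_fields__},
            fh, sort_keys=False, default_flow_style=False,
        )


def read_params(path) -> ScenarioParams:
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    raw["baseline_age_range"] = tuple(raw["baseline_age_range"])
    params = ScenarioParams(**raw)
    params.validate()
    return params
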