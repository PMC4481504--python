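"""End-to-end pipeline and the replicate simulation studies.

These are the operating characteristics the synthetic world is built to measure:
oracle recovery (bias and confidence-interval coverage of the weighted estimator
against the intervention-world truth), type-I error under the null scenario, and
the toward-null ordering of the conventional comparator against the MSM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import cohort, diagnostics, msm, prep, weights
from .msm import REPORT_ROWS

PARAM_NAMES = [name for name, _ in REPORT_ROWS]
EXPOSURE_PARAMS = [n for n in PARAM_NAMES if n.startswith("exposure[")]


def run_msm_pipeline(panel: pd.DataFrame, design: str = "M4",
                     censor_weights: bool = True,
                     truncation=(1.0, 99.0)) -> msm.MSMResult:
    """Exclusions -> person-periods -> stabilized weights -> weighted pooled fit."""
    pp, _ = prep.prepare(panel)
    if design == "M1":
        return msm.fit_msm(pp, weights=None, design="M1")
    pair = weights.fit_exposure_models(pp, design=design)
    cens = None
    if censor_weights and pp["censor"].sum() > 0:
        cens = weights.fit_censoring_models(pp, design=design)
    ws = weights.compute_stabilized_weights(pp, pair, censor_models=cens,
                                            truncation=truncation)
    return msm.fit_msm(pp, weights=ws, design=design)


def model_sequence(panel: pd.DataFrame, censor_weights: bool = True) -> list[msm.MSMResult]:
    """The incremental M1-M4 column sequence on one panel."""
    return [run_msm_pipeline(panel, design=d, censor_weights=censor_weights)
            for d in msm.MODEL_DESIGNS]


@dataclass
class ReplicateEstimates:
    """Point estimates and robust SEs per replicate for the 8 report parameters.

    ``n_failed`` counts replicates whose models could not be fit (separation or
    positivity on an unlucky draw); they are skipped, not imputed."""

    est: pd.DataFrame           # replicate x parameter (log-HR)
    se: pd.DataFrame
    naive_est: pd.DataFrame | None = None
    naive_se: pd.DataFrame | None = None
    n_failed: int = 0


def _extract(result: msm.MSMResult) -> tuple[pd.Series, pd.Series]:
    keep = [n for n in PARAM_NAMES if n in result.params.index]
    return result.params[keep], result.robust_se[keep]


def replicate_study(preset: str, n_subjects: int, n_replicates: int, seed: int,
                    design: str = "M4", naive: bool = False,
                    n_waves: int = 10, censor_weights: bool = True) -> ReplicateEstimates:
    """Repeatedly simulate, run the full pipeline, and collect estimates."""
    from .exceptions import WeightMSMError

    rng = np.random.default_rng(seed)
    est, ses, nest, nses = [], [], [], []
    n_failed = 0
    for _ in range(n_replicates):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        params = cohort.default_params(preset, n_subjects=n_subjects,
                                       n_waves=n_waves, seed=rep_seed)
        panel = cohort.simulate_cohort(params)
        try:
            res = run_msm_pipeline(panel, design=design,
                                   censor_weights=censor_weights)
            if naive:
                pp, _ = prep.prepare(panel)
                nres = diagnostics.fit_naive_timedep(pp, design=design)
        except WeightMSMError:
            n_failed += 1
            continue
        e, s = _extract(res)
        est.append(e)
        ses.append(s)
        if naive:
            ne, ns = _extract(nres)
            nest.append(ne)
            nses.append(ns)
    if not est:
        raise RuntimeError("every replicate failed to fit")
    out = ReplicateEstimates(est=pd.DataFrame(est).reset_index(drop=True),
                             se=pd.DataFrame(ses).reset_index(drop=True),
                             n_failed=n_failed)
    if naive:
        out.naive_est = pd.DataFrame(nest).reset_index(drop=True)
        out.naive_se = pd.DataFrame(nses).reset_index(drop=True)
    return out


def coverage_summary(reps: ReplicateEstimates, truth: pd.Series) -> dict:
    """95% CI coverage of the oracle truth, per parameter and pooled, plus bias."""
    cols = [c for c in reps.est.columns if c in truth.index]
    est, se = reps.est[cols], reps.se[cols]
    tr = truth[cols]
    lo, hi = est - 1.96 * se, est + 1.96 * se
    covered = (lo.le(tr, axis=1) & hi.ge(tr, axis=1))
    bias = est.mean() - tr
    return {
        "coverage_by_param": covered.mean().to_dict(),
        "coverage_pooled": float(covered.to_numpy().mean()),
        "bias_by_param": bias.to_dict(),
        "mean_abs_bias": float(bias.abs().mean()),
        "n_replicates": len(est),
        "mc_se_coverage_pooled": float(
            np.sqrt(0.95 * 0.05 / covered.size)),
    }


def type1_summary(reps: ReplicateEstimates) -> dict:
    """Per exposure category: fraction of replicates whose 95% CI excludes HR=1."""
    est, se = reps.est[EXPOSURE_PARAMS], reps.se[EXPOSURE_PARAMS]
    reject = (est.abs() > 1.96 * se)
    return {
        "reject_rate_by_param": reject.mean().to_dict(),
        "reject_rate_pooled": float(reject.to_numpy().mean()),
        "n_replicates": len(est),
    }


def toward_null_summary(reps: ReplicateEstimates,
                        params=("exposure[LargeLoss]", "exposure[SmallLoss]")) -> dict:
    """Fraction of replicates in which the naive comparator's log-HR is closer to 0."""
    if reps.naive_est is None:
        raise ValueError("replicates were run without the naive comparator")
    out = {}
    for p in params:
        closer = reps.naive_est[p].abs() < reps.est[p].abs()
        out[p] = float(closer.mean())
    out["all_params_min"] = float(min(out[p] for p in params))
    out["n_replicates"] = len(reps.est)
    return out
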