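"""Fit the weighted pooled hazard models: the incremental M1-M4 sequence, the
smoking- and baseline-weight-stratified fits, and the interaction fits.

Reads results/panel.csv (the sequence refits weights per design); writes the
hazard-ratio tables under results/.
"""

from pathlib import Path

import weightmsm as wm
from weightmsm import msm

OUT = Path(__file__).resolve().parents[1] / "results"

panel = wm.cohort.read_panel(OUT / "panel.csv")
results = wm.model_sequence(panel)
table = msm.hazard_ratio_table(results)
table.to_csv(OUT / "hazard_ratios_m1_m4.csv")
print("adjusted hazard ratios (weighted pooled hazard models), M1 -> M4:")
print(table.to_string())
print()

pp, _ = wm.prepare(panel)
strat = msm.stratified_fit(pp, "smoking_ever")
ok = {k: v for k, v in strat.items() if isinstance(v, msm.MSMResult)}
msm.hazard_ratio_table(list(ok.values())).to_csv(OUT / "stratified_smoking.csv")
print("large-loss HR by smoking stratum:",
      {k: round(v.hr("exposure[LargeLoss]"), 2) for k, v in ok.items()})

strat_bmi = msm.stratified_fit(pp, "baseline_bmi_category", collapse_obesity=True)
ok_bmi = {k: v for k, v in strat_bmi.items() if isinstance(v, msm.MSMResult)}
msm.hazard_ratio_table(list(ok_bmi.values())).to_csv(OUT / "stratified_baseline_bmi.csv")
for k, v in strat_bmi.items():
    if not isinstance(v, msm.MSMResult):
        print(f"stratum {k}: {v}")
print("large-loss HR by baseline weight stratum:",
      {k: round(v.hr("exposure[LargeLoss]"), 2) for k, v in ok_bmi.items()})

pair = wm.fit_exposure_models(pp, design="M4")
cens = wm.fit_censoring_models(pp, design="M4")
ws = wm.compute_stabilized_weights(pp, pair, censor_models=cens)
for interactor in ("smoking_ever", "baseline_bmi_category"):
    tab = msm.interaction_fit(pp, ws, interactor)
    tab.to_csv(OUT / f"interactions_{interactor}.csv")
    jw = tab.attrs["joint_wald"]
    print(f"{interactor} interactions: joint Wald p = {jw['p']:.3f} "
          f"(df {jw['df']}) — the generator encodes no effect modification")
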