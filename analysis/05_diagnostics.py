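"""Confounding-structure checks, descriptive tables, and the conventional
comparator side by side with the weighted estimates.

Reads results/panel.csv and results/person_periods.csv; writes the diagnostic
tables under results/.
"""

from pathlib import Path

import pandas as pd

import weightmsm as wm
from weightmsm import diagnostics

OUT = Path(__file__).resolve().parents[1] / "results"

panel = wm.cohort.read_panel(OUT / "panel.csv")
pp = pd.read_csv(OUT / "person_periods.csv")

tab1 = diagnostics.baseline_table(panel)
tab1.to_csv(OUT / "baseline_characteristics.csv")
print(f"baseline characteristics table: {tab1.shape[0]} rows x {tab1.shape[1]} "
      "membership columns (individuals can appear in several)")

tab2 = diagnostics.weight_change_by_health_table(pp)
tab2.to_csv(OUT / "weight_change_by_health.csv")
print("\nweight change by previous health status (column %):")
print(tab2.round(2).to_string())
for label, (stat, p) in tab2.attrs["chi_square"].items():
    print(f"  chi-square ({label}): {stat:.1f} (p = {p:.2g})")

report = diagnostics.confounding_checks(pp)
rows = []
for name, block in report.blocks().items():
    rows.append({"block": name, "outcome": block.outcome, "n": block.n_rows,
                 "association": block.association})
pd.DataFrame(rows).to_csv(OUT / "confounder_checks.csv", index=False)
print("\nconfounder-criteria checks (subject-clustered robust SEs):")
for r in rows:
    print(f"  {r['block']}: association detected = {r['association']}")

naive = diagnostics.fit_naive_timedep(pp, design="M4")
naive.hr_table.to_csv(OUT / "naive_timedep.csv")
msm_res = wm.run_msm_pipeline(panel, design="M4")
print("\nlarge weight loss HR — weighted MSM vs conventional time-dependent "
      "adjustment:")
print(f"  MSM   : {msm_res.hr('exposure[LargeLoss]'):.2f}")
print(f"  naive : {naive.hr('exposure[LargeLoss]'):.2f}  (closer to the null: "
      "conditioning on post-change illness adjusts away the mediated effect)")
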