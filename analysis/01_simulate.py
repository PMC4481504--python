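"""Simulate the study cohort: a confounded biennial panel with illness feedback.

Writes the long-format panel and its generating config under results/.
"""

from pathlib import Path

import weightmsm as wm

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

params = wm.default_params("confounded", n_subjects=6000, n_waves=10, seed=20260921)
panel = wm.simulate_cohort(params)
wm.cohort.write_panel(panel, OUT / "panel.csv")
wm.cohort.write_params(params, OUT / "panel.params.yaml")

n = panel["subject_id"].nunique()
deaths = panel.groupby("subject_id")["died_in_interval"].max().sum()
print(f"simulated {n} subjects over {params.n_waves} biennial waves "
      f"({len(panel)} person-waves)")
print(f"cumulative deaths: {deaths} ({100 * deaths / n:.1f}%)")
print(f"wrote {OUT / 'panel.csv'}")
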