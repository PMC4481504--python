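"""Exclusion cascade and person-period expansion of the simulated panel.

Reads results/panel.csv; writes the person-period table and the exclusion report.
"""

from pathlib import Path

import weightmsm as wm

OUT = Path(__file__).resolve().parents[1] / "results"

panel = wm.cohort.read_panel(OUT / "panel.csv")
pp, report = wm.prepare(panel)
pp.to_csv(OUT / "person_periods.csv", index=False)
report.write(OUT / "exclusion_report.tsv")

print("exclusion cascade (subjects counted once, at the first matching rule):")
for k, v in report.as_dict().items():
    print(f"  {k}: {v}")
print(f"person-period table: {len(pp)} rows, {pp['event'].sum()} deaths, "
      f"{pp['censor'].sum()} censorings")
print(f"wrote {OUT / 'person_periods.csv'}")
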