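#!/usr/bin/env python
"""Simulate 24-h oral estragole kinetics across the benchmark dose range.

Runs both population models at 0.01 (dietary), 5 (supplement), 150
(rodent-tumour) and 300 mg/kg bw and tabulates the %-of-dose converted to
each metabolite.  Writes results/dose_response.csv and the 0.01 mg/kg
time-course summaries (results/summary_<population>_0.01.json).
"""

from pathlib import Path

import pandas as pd

from estragole_pbk import build_model_spec, load_population, simulate
from estragole_pbk.io import write_summary_json
from estragole_pbk.pbk_core import METABOLITES

RESULTS = Path(__file__).resolve().parents[1] / "results"
RESULTS.mkdir(exist_ok=True)

DOSES = [0.01, 5.0, 150.0, 300.0]

rows = []
for population in ("chinese", "caucasian"):
    spec = build_model_spec(load_population(population))
    for dose in DOSES:
        res = simulate(spec, dose)
        rows.append({
            "population": population,
            "dose_mg_per_kg": dose,
            **{f"{m}_pct_of_dose": round(res.percent_of_dose[m], 4) for m in METABOLITES},
            "liver_HE_cmax_uM": round(res.liver_he_cmax_uM, 5),
            "liver_HE_auc_uM_h": round(res.liver_he_auc_uM_h, 5),
        })
        if dose == 0.01:
            write_summary_json(res, RESULTS / f"summary_{population}_0.01.json")

table = pd.DataFrame(rows)
table.to_csv(RESULTS / "dose_response.csv", index=False)
print(table[["population", "dose_mg_per_kg", "HE_pct_of_dose", "OE_pct_of_dose",
             "HEG_pct_of_dose", "HES_pct_of_dose"]].to_string(index=False))

low = table[table.dose_mg_per_kg == 0.01].set_index("population")
print(f"\nAt the dietary dose, 1'-hydroxyestragole formation is similar in the "
      f"two groups ({low.loc['chinese', 'HE_pct_of_dose']:.1f} vs "
      f"{low.loc['caucasian', 'HE_pct_of_dose']:.1f}% of dose), while "
      f"bioactivation to 1'-sulfooxyestragole is several-fold lower for the "
      f"Chinese parameterization ({low.loc['chinese', 'HES_pct_of_dose']:.3f} vs "
      f"{low.loc['caucasian', 'HES_pct_of_dose']:.3f}% of dose).")
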