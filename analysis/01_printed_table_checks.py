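"""Recompute the published diagnostic-accuracy and percent-of-control
numbers from the printed summary statistics alone.

The printed sensitivities (81.5 / 74.1 / 88.9%) share one denominator, as
do the specificities (80 / 70 / 85 / 75%); enumerating denominators
recovers the underlying confusion counts (27 affected and 20 control
eyes), from which the predictive values and exact Clopper-Pearson
intervals follow. Percent-of-control values follow directly from the
group means. Writes results/printed_checks.csv.
"""

from pathlib import Path

import pandas as pd

from octmorph import counts_from_rates, diagnostic_metrics, percent_of_control
from octmorph import reference as R

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

rows = []

n_pos, sens_x = counts_from_rates(sorted(set(R.PUBLISHED_SENSITIVITY)), max_n=40)
n_neg, spec_x = counts_from_rates(sorted(set(R.PUBLISHED_SPECIFICITY)), max_n=40)
print(f"printed sensitivities force {n_pos} affected eyes; "
      f"specificities force {n_neg} control eyes")

for (param, thr, direction), sens, spec in zip(
        R.FIXED_RULES, R.PUBLISHED_SENSITIVITY, R.PUBLISHED_SPECIFICITY):
    tp, tn = sens_x[sens], spec_x[spec]
    res = diagnostic_metrics(tp, n_neg - tn, n_pos - tp, tn)
    rows.append({
        "parameter": param, "threshold": thr,
        "tp": tp, "fn": n_pos - tp, "tn": tn, "fp": n_neg - tn,
        "sensitivity": res.sensitivity.value,
        "sens_lci": res.sensitivity.lower, "sens_uci": res.sensitivity.upper,
        "specificity": res.specificity.value,
        "spec_lci": res.specificity.lower, "spec_uci": res.specificity.upper,
        "ppv": res.ppv.value, "npv": res.npv.value,
    })
    print(f"{param:18s} thr {thr:>5}: sens {res.sensitivity.value:.1f} "
          f"({res.sensitivity.lower:.1f}-{res.sensitivity.upper:.1f})  "
          f"spec {res.specificity.value:.1f}  ppv {res.ppv.value:.1f}  "
          f"npv {res.npv.value:.2f}")

pd.DataFrame(rows).to_csv(OUT / "printed_checks.csv", index=False,
                          float_format="%.6g")

poc_rows = []
for label, case_stats, ctrl_stats in [("pcg", R.PCG, R.PCG_CONTROL),
                                      ("poag", R.POAG, R.POAG_CONTROL)]:
    for p in R.ONH_PARAMS + R.FOVEA_PARAMS:
        if p not in case_stats.params or p not in ctrl_stats.params:
            continue
        pct = percent_of_control([case_stats.params[p][0]],
                                 ctrl_stats.params[p][0], p).mean_pct
        poc_rows.append({"group": label, "parameter": p, "percent_of_control": pct})
poc = pd.DataFrame(poc_rows)
poc.to_csv(OUT / "percent_of_control_from_means.csv", index=False,
           float_format="%.6g")
key = poc.set_index(["group", "parameter"])["percent_of_control"]
print(f"\ncup depth: PCG {key['pcg', 'cup_depth_um']:.0f}% of control, "
      f"POAG {key['poag', 'cup_depth_um']:.0f}%")
print(f"cup diameter (PCG) {key['pcg', 'cup_diameter_deg']:.0f}%, "
      f"rim area (PCG) {key['pcg', 'rim_area_degum']:.1f}%, "
      f"foveal pit width (PCG) {key['pcg', 'foveal_pit_width_deg']:.0f}%")
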