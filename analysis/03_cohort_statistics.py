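"""Simulate the two study cohorts and run the statistical layer.

Cohorts are drawn from the published group summaries: 20 children with
congenital glaucoma (13 unilateral, matching the 27 affected eyes the
published sensitivities imply) vs 20 matched child controls, and 10 adult
open-angle-glaucoma patients vs 10 adult controls. Each parameter is
compared with the repeated-measures linear mixed model (group + eye +
age, random intercept per participant) with Bonferroni correction, and
expressed as percent of the control mean. Writes group_comparison_*.csv
and percent_of_control_*.csv under results/.
"""

from pathlib import Path

from octmorph import sample_cohort
from octmorph import reference as R
from octmorph.stats import group_table, percent_table

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)
SEED = 20260926

for label, case, ctrl, n_case, n_ctrl, uf in [
        ("pcg", R.PCG, R.PCG_CONTROL, 20, 20, 0.65),
        ("poag", R.POAG, R.POAG_CONTROL, 10, 10, 0.0)]:
    cohort = sample_cohort(case, ctrl, n_case, n_ctrl, unilateral_fraction=uf,
                           seed=SEED)
    cohort.to_csv(OUT / f"cohort_{label}.csv", index=False, float_format="%.6g")
    params = [p for p in R.ONH_PARAMS + R.FOVEA_PARAMS if p in cohort.columns]
    t2 = group_table(cohort, params, bonferroni_m=len(R.ONH_PARAMS))
    t2.to_csv(OUT / f"group_comparison_{label}.csv", index=False,
              float_format="%.6g")
    poc = percent_table(cohort, params)
    poc.to_csv(OUT / f"percent_of_control_{label}.csv", index=False,
               float_format="%.6g")
    sig = t2[t2["p_adjusted"] < 0.05]["parameter"].tolist()
    print(f"{label}: n_eyes={len(cohort)}, significant after Bonferroni: {sig}")
    cd = poc.set_index("parameter").loc["cup_depth_um", "mean_pct"]
    print(f"{label}: cup depth {cd:.0f}% of control mean")
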