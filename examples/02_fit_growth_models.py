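"""Fit the growth-model zoo to one plant and rank the candidates.

Leaf area follows a slow-fast-slow sigmoid, so the three classic sigmoids
(logistic, Gompertz, Richards) beat the linear/power/quadratic baselines;
curd area from appearance to harvest follows a rising sine half-period.
Ranking is by degrees-of-freedom-corrected RMSE.
"""

import caulipheno as cp
from caulipheno.models import CURD_MODELS, LEAF_MODELS

cohort = cp.simulate_cohort(seed=42)
pid = cohort.plant_ids[0]

print(f"leaf-area model ranking for {pid}:")
for fit in cp.compare_models(cohort.leaf_series[pid], LEAF_MODELS):
    print(f"  {fit.model:<10} R2={fit.r2:8.5f}  RMSE={fit.rmse:10.2f}  "
          f"chi2_red={fit.reduced_chi_sq:12.2f}")

print(f"\ncurd-area model ranking for {pid}:")
for fit in cp.compare_models(cohort.curd_series[pid], CURD_MODELS):
    print(f"  {fit.model:<11} R2={fit.r2:8.5f}  RMSE={fit.rmse:8.2f}  "
          f"chi2_red={fit.reduced_chi_sq:10.2f}")

best = cp.fit_model(cohort.leaf_series[pid], "richards")
print(f"\nbest Richards parameters: {best.params}")
print("a = asymptotic leaf area (cm^2), k = intrinsic rate (1/day), "
      "tc = day of peak growth rate, d = shape (d->1 Gompertz, d=2 logistic)")
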