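"""Generate a synthetic 47-germplasm cauliflower cohort and inspect it.

Builds the default cohort (47 germplasms x 3 replicates = 141 plants,
imaged every 3 days then daily once the first curd appears) and prints the
cohort structure plus one plant's leaf- and curd-area trajectories.
"""

import caulipheno as cp

cohort = cp.simulate_cohort(seed=42)

print(f"plants: {len(cohort.plant_ids)}")
print(f"germplasms: {cohort.truth['germplasm_id'].nunique()}")
print(f"archetype counts:\n{cohort.truth.drop_duplicates('germplasm_id')['archetype'].value_counts()}")
print(f"curd appearance range: day {cohort.truth['tca_true'].min():.0f}"
      f" to {cohort.truth['tca_true'].max():.0f}")

pid = cohort.plant_ids[0]
leaf = cohort.leaf_series[pid]
curd = cohort.curd_series[pid]
print(f"\nplant {pid}: {len(leaf)} leaf-area points, {len(curd)} curd-area points")
print(f"final leaf area {leaf.final_value:.0f} cm^2, final curd area {curd.final_value:.0f} cm^2")
# Every generating parameter is in the truth table, so any downstream
# estimate can be validated by recovery.
print(cohort.truth.head(3).to_string())
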