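"""Germplasm trait table, trait correlations and Ward clustering.

Derives the 14 season-summary traits per plant, averages the three
biological replicates into germplasm means, then computes Pearson
correlations and cuts a Ward/Euclidean tree on z-scored traits into four
groups — recovering the archetypes the cohort was generated from.
"""

import pandas as pd

import caulipheno as cp

cohort = cp.simulate_cohort(seed=42)
truth = cohort.truth.set_index("plant_id")

records = []
for pid in cohort.plant_ids:
    leaf, curd = cohort.leaf_series[pid], cohort.curd_series[pid]
    lfit = cp.fit_model(leaf, "richards")
    cfit = cp.fit_model(curd, "sine")
    kin = cp.rapid_growth_window(lfit)
    tca = float(truth.loc[pid, "tca_true"])
    stats = cp.curd_rate_stats(cfit, truth.loc[pid, "harvest_day"], tca=tca)
    rec = cp.derive_plant_traits(leaf, curd, kin, stats, tca)
    rec["germplasm_id"] = truth.loc[pid, "germplasm_id"]
    records.append(rec)

table = cp.aggregate_germplasm(pd.DataFrame(records))
print(f"germplasm trait table: {table.shape[0]} germplasms x "
      f"{len([c for c in cp.TRAIT_COLUMNS if c in table])} traits")

r, p = cp.correlation_matrix(table)
print(f"\nr(LA, PCW) = {r.loc['LA', 'PCW']:.2f}  (canopy scales with leaf area)")
print(f"r(CA, FCD) = {r.loc['CA', 'FCD']:.2f}  (curd size is internally consistent)")
print(f"r(ECEP, AER) = {r.loc['ECEP', 'AER']:.2f}  (faster expansion, shorter period)")

clusters = cp.cluster_germplasms(table, k=4)
arch = truth.drop_duplicates("germplasm_id").set_index("germplasm_id")["archetype"]
summary = pd.DataFrame({"group": clusters.labels, "archetype": arch})
print("\ncluster group vs generating archetype:")
print(summary.groupby(["group", "archetype"]).size().unstack(fill_value=0).to_string())
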