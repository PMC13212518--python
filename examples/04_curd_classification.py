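"""Classify curd harvest status from sine-fit growth kinetics.

The sine rate peaks at tc; the ratio of harvest-time rate to peak rate and
the rate trend at harvest give three kinetic types: steady climbing
(pre-peak - delaying harvest gains yield), peak burst (at the plateau -
optimal commercial harvest), mature and full (post-peak - harvest promptly).
"""

from collections import Counter

import caulipheno as cp

cohort = cp.simulate_cohort(seed=42)
truth = cohort.truth.set_index("plant_id")

labels = Counter()
for pid in cohort.plant_ids:
    fit = cp.fit_model(cohort.curd_series[pid], "sine")
    stats = cp.curd_rate_stats(fit, harvest_day=truth.loc[pid, "harvest_day"],
                               tca=truth.loc[pid, "tca_true"])
    labels[cp.classify_curd(stats)] += 1

n = sum(labels.values())
for label, count in labels.most_common():
    print(f"{label:<16} {count:3d}  ({100 * count / n:.1f}%)")

pid = cohort.plant_ids[0]
fit = cp.fit_model(cohort.curd_series[pid], "sine")
stats = cp.curd_rate_stats(fit, truth.loc[pid, "harvest_day"],
                           tca=truth.loc[pid, "tca_true"])
print(f"\nplant {pid}: harvest rate {stats.harvest_rate:.1f} cm^2/day "
      f"({100 * stats.rate_ratio:.0f}% of peak {stats.max_rate:.1f}), "
      f"trend {stats.trend_at_harvest} -> {cp.classify_curd(stats)}")
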