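"""Density controls: regression of consecutive proportion on global SO
density, and the epoch-based density-matched profile.

The regression uses mean-centered NREM density with a group interaction
(elderly and observed as reference categories); the three-way model adds the
observed-vs-randomized source factor. The epoch profile pools 30-s epochs
across subjects within group, bins them by local SO count, and averages the
per-epoch proportions (global labels aggregated, never recomputed per epoch).
"""

import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from _shared import RESULTS, get_cohort

from sotrains.density import epoch_density_profile, global_density_table
from sotrains.stats import ols_fit

cohort = get_cohort()
RESULTS.mkdir(parents=True, exist_ok=True)

table = global_density_table([row for r in cohort for row in r.density_rows()])
table.to_csv(RESULTS / "subject_density_table.csv", index=False)

obs = table[table["source"] == "observed"]
ols_obs = ols_fit(obs, "p_consecutive",
                  ["nrem_density", "group", "nrem_density:group"],
                  center=["nrem_density"], references={"group": "elderly"})
ols_full = ols_fit(table, "p_consecutive",
                   ["nrem_density", "group", "source",
                    "nrem_density:group", "nrem_density:source",
                    "group:source", "nrem_density:group:source"],
                   center=["nrem_density"],
                   references={"group": "elderly", "source": "observed"})
with open(RESULTS / "ols_results.json", "w") as fh:
    json.dump({"observed": ols_obs.as_dict(), "full": ols_full.as_dict()},
              fh, indent=1)

print("observed-data model (p_consecutive ~ density_c * group):")
for term in ols_obs.params.index:
    print(f"  {term:>22s}: {ols_obs.params[term]:+.4f} "
          f"(t = {ols_obs.tvalues[term]:.2f}, p = {ols_obs.pvalues[term]:.2g})")
print(f"  R² = {ols_obs.r_squared:.3f}")
print("\nthree-way model adds source (observed vs randomized):")
t3 = "nrem_density:group:source"
print(f"  {t3}: {ols_full.params[t3]:+.4f} "
      f"(t = {ols_full.tvalues[t3]:.2f}, p = {ols_full.pvalues[t3]:.2g}); "
      f"R² = {ols_full.r_squared:.3f}")

for g in ("young", "elderly"):
    events = pd.concat([r.events for r in cohort if r.group == g],
                       ignore_index=True)
    prof = epoch_density_profile(events)
    prof.to_csv(RESULTS / f"epoch_profile_{g}.csv", index=False)
    mid = prof[prof["density_bin"].between(4, 9)]
    print(f"\n{g}: mean p_consecutive in 4-9 SOs/epoch bins = "
          f"{mid['p_consecutive'].mean():.3f} "
          f"({int(mid['n_epochs'].sum())} epochs)")
print(f"\nwrote subject_density_table.csv, ols_results.json, "
      f"epoch_profile_*.csv under {RESULTS}")
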