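"""Sleep architecture and band-power validation of the synthetic cohort.

Standard descriptive metrics (TST, WASO, stage percentages, latencies,
awakenings, fragmentation index) and Welch band powers per stage, exported as
tidy tables for external statistics.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from _shared import RESULTS, get_cohort

cohort = get_cohort()
RESULTS.mkdir(parents=True, exist_ok=True)

sleep = pd.DataFrame([{"subject": r.subject, "group": r.group, **r.sleep}
                      for r in cohort])
sleep.round(3).to_csv(RESULTS / "sleep_metrics.csv", index=False)

bp = pd.concat([r.band_power.assign(group=r.group) for r in cohort
                if r.band_power is not None], ignore_index=True)
bp.round(4).to_csv(RESULTS / "band_power.csv", index=False)

cols = ["tst", "waso", "sfi", "awakenings", "pct_tst_SWS", "pct_tst_REM"]
print("sleep architecture (group means):")
print(sleep.groupby("group")[cols].mean().round(2).to_string())
print("\nband power (µV², group × stage means):")
print(bp.groupby(["group", "stage"])[["so", "delta", "alpha", "fast_spindle"]]
      .mean().round(1).to_string())
print(f"\nwrote sleep_metrics.csv, band_power.csv under {RESULTS}")
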