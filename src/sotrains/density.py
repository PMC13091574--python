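"""Density-control analyses.

Two complementary controls for the confound that clustering metrics depend on
how many SOs there are per minute:

1. the *global* control relates each subject's NREM SO density (waves/minute
   of artifact-free NREM) to their proportion of consecutive SOs, for the
   observed data and for the shuffled surrogate, feeding the interaction
   regressions; and
2. the *epoch-based* control pools 30-s NREM epochs across subjects within a
   group, bins them by local SO count, and averages the per-epoch proportion
   of isolated/consecutive SOs per bin — comparing groups at matched local
   density.

Event labels are taken from the global NREM classification and aggregated per
epoch; they are never recomputed within an epoch, since an SO can be
consecutive with a neighbor lying in the adjacent epoch. Events are assigned
to the epoch containing their negative peak.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MIN_EPOCHS_CI = 10  # bins with fewer pooled epochs get no confidence interval


def global_density_table(subject_rows: list[dict]) -> pd.DataFrame:
    """Tidy per-subject table of NREM density vs. consecutive proportion.

    Each input dict carries: subject, group, dataset, n_events, nrem_minutes,
    p_consecutive and source ('observed' | 'randomized'). Subjects with zero
    NREM minutes are skipped with a warning.
    """
    rows = []
    for r in subject_rows:
        if r["nrem_minutes"] <= 0:
            logger.warning("subject %s has no artifact-free NREM time; skipped",
                           r.get("subject"))
            continue
        rows.append({
            "subject": r["subject"],
            "group": r["group"],
            "dataset": r.get("dataset", "synthetic"),
            "nrem_density": r["n_events"] / r["nrem_minutes"],
            "p_consecutive": r["p_consecutive"],
            "source": r.get("source", "observed"),
        })
    df = pd.DataFrame(rows, columns=["subject", "group", "dataset",
                                     "nrem_density", "p_consecutive", "source"])
    if len(df) and ((df["p_consecutive"] < 0).any() or (df["p_consecutive"] > 1).any()):
        raise ValueError("p_consecutive outside [0, 1]")
    return df


def epoch_density_profile(
    labeled_events: pd.DataFrame,
    min_epochs_ci: int = MIN_EPOCHS_CI,
) -> pd.DataFrame:
    """Mean isolated/consecutive proportions per local-density bin.

    ``labeled_events`` needs columns epoch, label and (when pooling several
    subjects) subject. Epochs with zero events carry no proportion and are
    excluded by construction. The 95% CI uses a normal approximation over
    epochs and is suppressed (NaN) when a bin has fewer than
    ``min_epochs_ci`` epochs.
    """
    ev = labeled_events.copy()
    if "subject" not in ev.columns:
        ev["subject"] = "s0"
    per_epoch = (
        ev.assign(is_isolated=(ev["label"] == "isolated").astype(float))
        .groupby(["subject", "epoch"])
        .agg(n_events=("label", "size"), p_isolated=("is_isolated", "mean"))
        .reset_index()
    )
    rows = []
    for n_so, grp in per_epoch.groupby("n_events"):
        p = grp["p_isolated"].to_numpy()
        mean_iso = float(p.mean())
        n_ep = len(p)
        if n_ep >= min_epochs_ci:
            half = 1.96 * p.std(ddof=1) / np.sqrt(n_ep) if n_ep > 1 else 0.0
            ci_low, ci_high = mean_iso - half, mean_iso + half
        else:
            ci_low = ci_high = np.nan
        rows.append({
            "density_bin": int(n_so),
            "p_isolated": mean_iso,
            "p_consecutive": 1.0 - mean_iso,
            "n_epochs": n_ep,
            "ci_low": ci_low,
            "ci_high": ci_high,
        })
    return pd.DataFrame(rows).sort_values("density_bin", ignore_index=True)
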