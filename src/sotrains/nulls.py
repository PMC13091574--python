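"""Density-preserving temporal randomization of SO events.

The surrogate destroys the temporal clustering of detected SOs while keeping
the number of SOs per unit time *within each sleep stage* exactly as
observed: for every repetition, each stage's negative-peak times are redrawn
uniformly at random over that stage's artifact-free mask intervals
(time-weighted across intervals), re-drawing any candidate that lands closer
than ``min_isoi`` (0.5 s, the shortest interval seen in real data) to an
already placed time. The minimum-gap constraint is enforced on the global
timeline across stages because ISOIs and the classification are computed
globally. Surrogates carry only event times: the control analyzes temporal
structure, not waveforms.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classification import (DELTA_DEFAULT, ISOIHistogram, classify_events,
                             compute_isoi, isoi_histogram,
                             mean_train_length_density, train_length_density)
from .io import AnalysisMask

_RETRY_CAP = 10_000  # rejections allowed per repetition before giving up


class FeasibilityError(Exception):
    """Requested event count cannot be packed under the min-ISOI constraint."""


@dataclass(frozen=True)
class ShuffleParams:
    min_isoi: float = 0.5
    n_reps: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_isoi <= 0:
            raise ValueError("min_isoi must be positive")
        if self.n_reps < 1:
            raise ValueError("n_reps must be at least 1")


def _stage_counts(events, mask: AnalysisMask) -> dict[str, int]:
    if isinstance(events, pd.DataFrame) and "stage" in events.columns:
        return {s: int((events["stage"] == s).sum())
                for s in np.unique(mask.stages)}
    # bare times: infer stage from mask containment
    t = np.asarray(events if not isinstance(events, pd.DataFrame)
                   else events["t_negpeak"], dtype=float)
    counts: dict[str, int] = {}
    for s in np.unique(mask.stages):
        sel = mask.stages == s
        inside = np.zeros(t.size, dtype=bool)
        for lo, hi in mask.intervals[sel]:
            inside |= (t >= lo) & (t < hi)
        counts[s] = int(inside.sum())
    return counts


def _draw_uniform(intervals: np.ndarray, rng: np.random.Generator) -> float:
    """One time drawn uniformly over a union of intervals (time-weighted)."""
    lengths = intervals[:, 1] - intervals[:, 0]
    cum = np.cumsum(lengths)
    u = rng.uniform(0, cum[-1])
    k = int(np.searchsorted(cum, u, side="right"))
    return float(intervals[k, 0] + (u - (cum[k] - lengths[k])))


def shuffle_events(events, mask: AnalysisMask, params: ShuffleParams) -> list[np.ndarray]:
    """Randomized negative-peak time sets, one sorted array per repetition."""
    counts = _stage_counts(events, mask)
    for stage, n in counts.items():
        avail = mask.stage_seconds(stage)
        if n * params.min_isoi > avail:
            raise FeasibilityError(
                f"{n} events at min ISOI {params.min_isoi}s exceed the "
                f"{avail:.0f}s of {stage} time"
            )
    rng = np.random.default_rng(params.seed)
    stage_intervals = {s: mask.intervals[mask.stages == s] for s in counts}
    reps = []
    for _ in range(params.n_reps):
        placed: list[float] = []
        rejections = 0
        for stage, n in counts.items():
            iv = stage_intervals[stage]
            for _ in range(n):
                while True:
                    t = _draw_uniform(iv, rng)
                    k = bisect.bisect_left(placed, t)
                    ok = (k == 0 or t - placed[k - 1] >= params.min_isoi) and \
                         (k == len(placed) or placed[k] - t >= params.min_isoi)
                    if ok:
                        placed.insert(k, t)
                        break
                    rejections += 1
                    if rejections > _RETRY_CAP:
                        raise FeasibilityError(
                            "retry cap exceeded while placing shuffled events"
                        )
        reps.append(np.asarray(placed))
    return reps


def randomized_metrics(
    events,
    mask: AnalysisMask,
    params: ShuffleParams,
    delta: float = DELTA_DEFAULT,
    bin_width: float = 0.5,
    max_isoi: float = 30.0,
) -> dict:
    """Classification metrics of each shuffle repetition plus their means.

    Seeded runs are reproducible. Returns per-repetition p_isolated /
    p_consecutive, their means, the across-repetition mean train-length
    density (zero-padded) and the mean ISOI density histogram.
    """
    reps = shuffle_events(events, mask, params)
    p_iso, p_con, tl_dens, hists = [], [], [], []
    for times in reps:
        c = classify_events(times, delta=delta)
        p_iso.append(c.p_isolated)
        p_con.append(c.p_consecutive)
        tl_dens.append(train_length_density(c))
        hists.append(isoi_histogram(compute_isoi(times), bin_width, max_isoi))
    mean_hist_density = np.mean([h.density for h in hists], axis=0)
    mean_hist = ISOIHistogram(hists[0].bin_edges, mean_hist_density,
                              int(np.mean([h.n for h in hists])))
    return {
        "per_rep": {"p_isolated": p_iso, "p_consecutive": p_con},
        "p_isolated": float(np.mean(p_iso)),
        "p_consecutive": float(np.mean(p_con)),
        "train_length_density": mean_train_length_density(tl_dens),
        "isoi_histogram": mean_hist,
        "times": reps,
    }
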