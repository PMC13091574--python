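"""Temporal classification of slow oscillations: isolated events vs. trains.

The inter-SO interval (ISOI) is the time between negative peaks of successive
detected SOs. Given a threshold δ (default 2 s, the upper limit of the SO
period for a 0.5–1 Hz rhythm), an SO is *consecutive* when it lies within δ
seconds of its preceding or following SO, and *isolated* otherwise. A *train*
is a maximal run of events whose successive gaps are all ≤ δ; its length is
the number of SOs it contains (always ≥ 2). Events exactly δ apart count as
consecutive (the ≤/> convention has to be fixed somewhere; ties are
measure-zero in continuous data).

Proportions are reported relative to the total number of detections, and
train-length histograms are density-normalized, so both are comparable across
subjects with different detection counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DELTA_DEFAULT = 2.0

#: default δ-sensitivity grid: 0.5–10 s in 0.25-s steps
DELTA_GRID = np.round(np.arange(0.5, 10.0 + 1e-9, 0.25), 4)


def _negpeaks(events) -> np.ndarray:
    """Accept an event table or a bare array of negative-peak times."""
    if isinstance(events, pd.DataFrame):
        t = events["t_negpeak"].to_numpy(dtype=float)
    else:
        t = np.asarray(events, dtype=float)
    return t


@dataclass
class Classification:
    """Per-event labels and train structure at one δ."""

    labels: np.ndarray            # 'isolated' | 'consecutive'
    train_id: np.ndarray          # 0-based id per event, -1 for isolated
    train_lengths: np.ndarray     # one entry per train, each ≥ 2
    delta: float
    scope: str = "NREM"

    @property
    def n_events(self) -> int:
        return int(self.labels.size)

    @property
    def n_isolated(self) -> int:
        return int((self.labels == "isolated").sum())

    @property
    def n_consecutive(self) -> int:
        return int((self.labels == "consecutive").sum())

    @property
    def p_isolated(self) -> float:
        return self.n_isolated / self.n_events if self.n_events else np.nan

    @property
    def p_consecutive(self) -> float:
        return self.n_consecutive / self.n_events if self.n_events else np.nan

    def summary(self) -> dict:
        return {
            "delta": self.delta,
            "scope": self.scope,
            "n_events": self.n_events,
            "n_isolated": self.n_isolated,
            "n_consecutive": self.n_consecutive,
            "p_isolated": self.p_isolated,
            "p_consecutive": self.p_consecutive,
            "n_trains": int(self.train_lengths.size),
            "train_length_density": {
                int(k): float(v) for k, v in train_length_density(self).items()
            },
        }


def compute_isoi(events) -> np.ndarray:
    """Intervals between successive negative peaks, in seconds.

    Requires time-sorted input (raises otherwise); returns an empty array for
    fewer than two events.
    """
    t = _negpeaks(events)
    if t.size < 2:
        return np.array([])
    d = np.diff(t)
    if np.any(d < 0):
        raise ValueError("events must be sorted by negative-peak time")
    return d


def classify_events(events, delta: float = DELTA_DEFAULT, scope: str = "NREM") -> Classification:
    """Label each SO isolated/consecutive at threshold δ and extract trains."""
    if delta <= 0:
        raise ValueError("delta must be positive")
    t = _negpeaks(events)
    n = t.size
    if n == 0:
        return Classification(np.array([], dtype="<U11"), np.array([], dtype=int),
                              np.array([], dtype=int), delta, scope)
    gaps = compute_isoi(t)
    near_prev = np.concatenate([[False], gaps <= delta])
    near_next = np.concatenate([gaps <= delta, [False]])
    consec = near_prev | near_next
    labels = np.where(consec, "consecutive", "isolated").astype("<U11")

    train_id = np.full(n, -1, dtype=int)
    lengths: list[int] = []
    tid = 0
    i = 0
    while i < n:
        if i < n - 1 and gaps[i] <= delta:
            j = i
            while j < n - 1 and gaps[j] <= delta:
                j += 1
            train_id[i : j + 1] = tid
            lengths.append(j + 1 - i)
            tid += 1
            i = j + 1
        else:
            i += 1
    return Classification(labels, train_id, np.array(lengths, dtype=int), delta, scope)


def train_length_density(c: Classification) -> pd.Series:
    """Density over train lengths: count of trains of length L / total trains."""
    if c.train_lengths.size == 0:
        return pd.Series(dtype=float)
    vals, counts = np.unique(c.train_lengths, return_counts=True)
    return pd.Series(counts / counts.sum(), index=vals.astype(int))


def mean_train_length_density(densities: list[pd.Series]) -> pd.Series:
    """Group-level curve: mean of per-subject densities, zero-padded to the
    longest observed train."""
    nonempty = [d for d in densities if len(d)]
    if not nonempty:
        return pd.Series(dtype=float)
    lmax = max(int(d.index.max()) for d in nonempty)
    idx = np.arange(2, lmax + 1)
    padded = [d.reindex(idx, fill_value=0.0) for d in densities]
    return pd.concat(padded, axis=1).mean(axis=1)


@dataclass
class ISOIHistogram:
    """Density-normalized ISOI histogram with fixed-width bins from 0."""

    bin_edges: np.ndarray
    density: np.ndarray
    n: int

    def peak_bin(self, exclude_overflow: bool = True) -> tuple[float, float]:
        """(left edge of the highest-density bin, its density).

        The final bin pools all intervals beyond the histogram range; by
        default it does not compete for the peak.
        """
        dens = self.density[:-1] if exclude_overflow else self.density
        k = int(np.argmax(dens))
        return float(self.bin_edges[k]), float(self.density[k])

    def bin_density(self, left_edge: float) -> float:
        k = int(np.searchsorted(self.bin_edges, left_edge + 1e-12) - 1)
        return float(self.density[k])


def isoi_histogram(intervals, bin_width: float = 0.5, max_isoi: float = 30.0) -> ISOIHistogram:
    """Histogram of ISOIs on [0, max_isoi) with intervals ≥ max_isoi pooled
    into the final bin, which stays inside the density normalization."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    x = np.asarray(intervals, dtype=float)
    if np.any(x < 0):
        raise ValueError("ISOIs must be non-negative")
    edges = np.arange(0.0, max_isoi + bin_width / 2, bin_width)
    if x.size == 0:
        return ISOIHistogram(edges, np.zeros(edges.size - 1), 0)
    clipped = np.minimum(x, edges[-2] + bin_width / 2)  # pool overflow into last bin
    counts, _ = np.histogram(clipped, bins=edges)
    density = counts / (x.size * bin_width)
    return ISOIHistogram(edges, density, int(x.size))


def mean_isoi_histogram(hists: list[ISOIHistogram]) -> ISOIHistogram:
    """Mean of per-subject density histograms (equal weight per subject)."""
    if not hists:
        raise ValueError("no histograms to average")
    edges = hists[0].bin_edges
    for h in hists[1:]:
        if not np.array_equal(h.bin_edges, edges):
            raise ValueError("histograms must share bin edges")
    dens = np.mean([h.density for h in hists], axis=0)
    return ISOIHistogram(edges, dens, int(sum(h.n for h in hists)))


def delta_sweep(events, grid=DELTA_GRID) -> pd.DataFrame:
    """Rerun the classification over a δ grid.

    Returns a DataFrame with columns delta, p_isolated, p_consecutive;
    p_consecutive is non-decreasing in δ by construction.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty delta grid")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("delta grid must be strictly increasing")
    t = _negpeaks(events)
    rows = []
    for d in grid:
        c = classify_events(t, delta=float(d))
        rows.append({"delta": float(d), "p_isolated": c.p_isolated,
                     "p_consecutive": c.p_consecutive})
    return pd.DataFrame(rows)


def attach_labels(events: pd.DataFrame, c: Classification) -> pd.DataFrame:
    """Event table with label / train_id / train_len columns appended."""
    out = events.copy()
    out["label"] = c.labels
    out["train_id"] = c.train_id
    tl = np.full(len(out), 0, dtype=int)
    for tid, ln in enumerate(c.train_lengths):
        tl[c.train_id == tid] = ln
    out["train_len"] = tl
    return out
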