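"""Slow-oscillation detection by zero-crossing segmentation.

The detector follows the classic fixed-threshold scheme: the trace is
narrow-band filtered to the SO range (0.3–1.5 Hz, zero-phase FIR, 0.2 Hz
transitions), zero crossings are located, and each candidate wave is the
stretch from a positive-to-negative crossing (wave start), through the next
negative-to-positive crossing (mid-crossing), to the following
positive-to-negative crossing (wave end). A candidate is kept when

* the negative half-wave lasts 0.3–1.5 s,
* the positive half-wave lasts 0.1–1.0 s,
* the negative peak is at or below −40 µV, and
* the peak-to-peak (trough-to-crest) amplitude reaches the group threshold
  (75 µV for young adults, 60 µV for elderly — a fixed study input, not
  inferred from data),

and when the whole wave lies inside one artifact-free S2/SWS span (contiguous
same-stage epochs are merged before the containment test). All waveform
features are measured on the narrow-band signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import EPOCH_LEN, AnalysisMask, Hypnogram, Recording

#: columns of the detected-event table
EVENT_COLUMNS = [
    "t_start", "t_negpeak", "t_mid", "t_pospeak", "t_end",
    "A", "B", "C", "D", "ptp", "slope", "freq", "stage", "epoch",
]

PTP_MIN = {"young": 75.0, "elderly": 60.0}


@dataclass(frozen=True)
class DetectionParams:
    """Fixed detection criteria.

    ``ptp_min`` defaults to the young-adult threshold; use
    ``DetectionParams.for_group("elderly")`` for the lower elderly threshold.
    """

    filt_band: tuple[float, float] = (0.3, 1.5)
    dur_neg: tuple[float, float] = (0.3, 1.5)
    dur_pos: tuple[float, float] = (0.1, 1.0)
    neg_peak_max: float = -40.0
    ptp_min: float = 75.0

    def __post_init__(self) -> None:
        if not (0 < self.dur_neg[0] < self.dur_neg[1]):
            raise ValueError("dur_neg range must be positive and ordered")
        if not (0 < self.dur_pos[0] < self.dur_pos[1]):
            raise ValueError("dur_pos range must be positive and ordered")
        if self.neg_peak_max >= 0:
            raise ValueError("neg_peak_max must be negative")
        if self.ptp_min <= 0:
            raise ValueError("ptp_min must be positive")

    @classmethod
    def for_group(cls, group: str, **kw) -> "DetectionParams":
        return cls(ptp_min=PTP_MIN[group], **kw)


def narrowband(rec: Recording, band: tuple[float, float] = (0.3, 1.5)) -> Recording:
    """Zero-phase FIR filter to the SO band with 0.2 Hz transition bands."""
    import mne

    if rec.rate < 4 * band[1]:
        raise ValueError(f"sampling rate {rec.rate} Hz too low for band {band}")
    out = mne.filter.filter_data(
        rec.samples.astype(float), sfreq=rec.rate,
        l_freq=band[0], h_freq=band[1],
        l_trans_bandwidth=0.2, h_trans_bandwidth=0.2,
        method="fir", phase="zero", fir_design="firwin", verbose="error",
    )
    return Recording(np.asarray(out), rec.rate, rec.channel, rec.t0)


def _zero_crossings(x: np.ndarray, rate: float, t0: float):
    """Interpolated times of sign changes, split by direction.

    Returns (down, up): crossings from >0 to ≤0 and from <0 to ≥0.
    """
    s = np.sign(x)
    # exact zeros inherit the previous sign so each transition is unique
    zero = s == 0
    if zero.any():
        idxnz = np.nonzero(~zero)[0]
        if idxnz.size == 0:
            return np.array([]), np.array([])
        filled = np.maximum.accumulate(np.where(zero, -1, np.arange(s.size)))
        valid = filled >= 0
        s[valid] = s[np.clip(filled, 0, None)][valid]
    idx = np.nonzero(s[:-1] != s[1:])[0]
    denom = x[idx] - x[idx + 1]
    frac = np.where(denom != 0, x[idx] / np.where(denom == 0, 1.0, denom), 0.0)
    t = t0 + (idx + frac) / rate
    down = t[s[idx + 1] < 0]
    up = t[s[idx + 1] > 0]
    return down, up


def detect_sos(
    rec: Recording,
    mask: AnalysisMask,
    params: DetectionParams = DetectionParams(),
    prefiltered: bool = False,
) -> pd.DataFrame:
    """Detect slow oscillations inside the analysis mask.

    ``rec`` should already be broadband-filtered; the SO narrow-band filter is
    applied here unless ``prefiltered`` marks the input as already being in
    the SO band. Returns a DataFrame with :data:`EVENT_COLUMNS`, sorted by
    negative-peak time.
    """
    if len(mask) == 0:
        return pd.DataFrame(columns=EVENT_COLUMNS)
    nb = rec if prefiltered else narrowband(rec, params.filt_band)
    x = nb.samples
    rate, t0 = nb.rate, nb.t0
    down, up = _zero_crossings(x, rate, t0)
    if down.size < 2 or up.size < 1:
        return pd.DataFrame(columns=EVENT_COLUMNS)

    merged = mask.merged()
    rows = []
    # each wave: down-crossing, next up-crossing, next down-crossing
    for k in range(down.size - 1):
        t_start = down[k]
        j = np.searchsorted(up, t_start, side="right")
        if j >= up.size:
            break
        t_mid = up[j]
        t_end = down[k + 1]
        if not (t_start < t_mid < t_end):
            continue
        if not (params.dur_neg[0] <= t_mid - t_start <= params.dur_neg[1]):
            continue
        if not (params.dur_pos[0] <= t_end - t_mid <= params.dur_pos[1]):
            continue
        i0 = int(np.ceil((t_start - t0) * rate))
        i1 = int(np.floor((t_mid - t0) * rate))
        i2 = int(np.floor((t_end - t0) * rate))
        if i1 <= i0 or i2 <= i1:
            continue
        neg_seg = x[i0 : i1 + 1]
        pos_seg = x[i1 : i2 + 1]
        C = float(neg_seg.min())
        D = float(pos_seg.max())
        if C > params.neg_peak_max or (D - C) < params.ptp_min:
            continue
        iv = merged.contains(t_start, t_end)[0]
        if iv < 0:
            continue
        t_negpeak = t0 + (i0 + int(neg_seg.argmin())) / rate
        t_pospeak = t0 + (i1 + int(pos_seg.argmax())) / rate
        A = t_end - t_start
        B = t_mid - t_negpeak
        rows.append({
            "t_start": t_start, "t_negpeak": t_negpeak, "t_mid": t_mid,
            "t_pospeak": t_pospeak, "t_end": t_end,
            "A": A, "B": B, "C": C, "D": D, "ptp": D - C,
            "slope": abs(C) / B if B > 0 else np.nan, "freq": 1.0 / A,
            "stage": str(merged.stages[iv]),
            "epoch": int(t_negpeak // EPOCH_LEN),
        })
    events = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    return events.sort_values("t_negpeak", ignore_index=True)


FEATURES = ["A", "B", "C", "D", "ptp", "slope", "freq"]


def so_summary(events: pd.DataFrame, h: Hypnogram) -> dict:
    """Per-stage counts and densities plus per-subject waveform feature means.

    Densities are waves per minute of artifact-free time in the stage; the
    overall NREM density uses artifact-free S2+SWS minutes.
    """
    out: dict = {"n_total": int(len(events))}
    minutes = {s: h.stage_minutes(s, artifact_free=True) for s in ("S2", "SWS")}
    for stage in ("S2", "SWS"):
        n = int((events["stage"] == stage).sum()) if len(events) else 0
        if n and minutes[stage] == 0:
            raise ValueError(f"events in {stage} but no artifact-free {stage} time")
        out[f"n_{stage}"] = n
        out[f"density_{stage}"] = n / minutes[stage] if minutes[stage] > 0 else 0.0
        out[f"prop_{stage}"] = n / len(events) if len(events) else np.nan
    nrem_min = minutes["S2"] + minutes["SWS"]
    out["nrem_minutes"] = nrem_min
    out["density_nrem"] = out["n_total"] / nrem_min if nrem_min > 0 else 0.0
    for feat in FEATURES:
        out[f"mean_{feat}"] = float(events[feat].mean()) if len(events) else np.nan
    return out
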