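"""Sleep-architecture metrics and Welch band-power analysis.

These are the standard descriptive measures used to check that a cohort shows
the expected sleep physiology: total sleep time (TST), wake after sleep onset
(WASO), stage minutes and percentages, SWS/REM latencies from onset, number
of awakenings, and a sleep fragmentation index (SFI = awakenings + shifts to
stage 1 from deeper sleep or REM, per hour of TST). Sleep onset is the first
stage-2 epoch.

Spectra use Welch's method on 10-s blocks with 50% overlap and a single Hann
taper, giving 0.1 Hz resolution without zero padding; blocks are drawn only
from within contiguous artifact-free same-stage spans. Band power is the
trapezoid integral of the mean spectrum over the band. Band definitions
overlap (alpha 8–13 vs. slow spindles 9–12) and are reported as-is.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import AnalysisMask, Hypnogram, Recording

#: frequency bands in Hz
BANDS = {
    "so": (0.5, 1.0),
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "slow_spindle": (9.0, 12.0),
    "fast_spindle": (12.0, 15.0),
    "beta": (15.0, 30.0),
}

SLEEP_STAGES = ("S1", "S2", "SWS", "REM")


@dataclass
class SleepMetrics:
    tst: float                      # minutes
    waso: float                     # minutes
    stage_minutes: dict             # per sleep stage + NREM
    stage_pct_tst: dict             # % of TST per sleep stage + NREM
    pct_nrem: dict                  # S2 and SWS as % of NREM
    sws_latency: float | None       # minutes from onset
    rem_latency: float | None
    awakenings: int
    shifts_to_s1: int
    sfi: float | None               # events per hour of TST
    onset_epoch: int | None

    def as_dict(self) -> dict:
        d = {
            "tst": self.tst, "waso": self.waso,
            "sws_latency": self.sws_latency, "rem_latency": self.rem_latency,
            "awakenings": self.awakenings, "shifts_to_s1": self.shifts_to_s1,
            "sfi": self.sfi, "onset_epoch": self.onset_epoch,
        }
        d.update({f"min_{k}": v for k, v in self.stage_minutes.items()})
        d.update({f"pct_tst_{k}": v for k, v in self.stage_pct_tst.items()})
        d.update({f"pct_nrem_{k}": v for k, v in self.pct_nrem.items()})
        return d


def sleep_metrics(h: Hypnogram) -> SleepMetrics:
    """Architecture metrics from a unified hypnogram at 0.5 min/epoch."""
    if not h.is_unified():
        raise ValueError("hypnogram must be unified")
    stages = h.stages
    epmin = h.epoch_len / 60.0

    minutes = {s: float((stages == s).sum()) * epmin for s in SLEEP_STAGES}
    minutes["NREM"] = minutes["S2"] + minutes["SWS"]
    tst = sum(minutes[s] for s in SLEEP_STAGES)

    onset_idx = np.nonzero(stages == "S2")[0]
    onset = int(onset_idx[0]) if onset_idx.size else None

    prev, nxt = stages[:-1], stages[1:]
    sleep_set = np.isin(prev, SLEEP_STAGES)
    awakenings = int((sleep_set & (nxt == "W")).sum())
    shifts = int((np.isin(prev, ("S2", "SWS", "REM")) & (nxt == "S1")).sum())

    if onset is None or tst == 0:
        return SleepMetrics(tst=tst, waso=np.nan, stage_minutes=minutes,
                            stage_pct_tst={k: np.nan for k in minutes},
                            pct_nrem={"S2": np.nan, "SWS": np.nan},
                            sws_latency=None, rem_latency=None,
                            awakenings=awakenings, shifts_to_s1=shifts,
                            sfi=None, onset_epoch=onset)

    waso = float((stages[onset:] == "W").sum()) * epmin
    pct_tst = {k: 100.0 * v / tst for k, v in minutes.items()}
    nrem = minutes["NREM"]
    pct_nrem = {s: (100.0 * minutes[s] / nrem if nrem > 0 else np.nan)
                for s in ("S2", "SWS")}

    def latency(stage: str) -> float | None:
        idx = np.nonzero(stages[onset:] == stage)[0]
        return float(idx[0]) * epmin if idx.size else None

    sfi = (awakenings + shifts) / (tst / 60.0)
    return SleepMetrics(tst=tst, waso=waso, stage_minutes=minutes,
                        stage_pct_tst=pct_tst, pct_nrem=pct_nrem,
                        sws_latency=latency("SWS"), rem_latency=latency("REM"),
                        awakenings=awakenings, shifts_to_s1=shifts,
                        sfi=sfi, onset_epoch=onset)


def _welch_blocks(x: np.ndarray, rate: float, block_s: float = 10.0):
    """Hann-tapered one-sided periodograms of 50%-overlapping blocks."""
    nper = int(round(block_s * rate))
    step = nper // 2
    if x.size < nper:
        return None, []
    win = np.hanning(nper)
    norm = rate * (win ** 2).sum()
    freqs = np.fft.rfftfreq(nper, d=1.0 / rate)
    specs = []
    for start in range(0, x.size - nper + 1, step):
        seg = x[start : start + nper]
        seg = (seg - seg.mean()) * win
        p = (np.abs(np.fft.rfft(seg)) ** 2) / norm
        p[1:-1] *= 2.0  # one-sided
        specs.append(p)
    return freqs, specs


def band_power(
    rec: Recording,
    mask: AnalysisMask,
    bands: dict[str, tuple[float, float]] = BANDS,
    block_s: float = 10.0,
) -> dict[str, float] | None:
    """Band powers (µV²) for one stage's mask via Welch's method.

    Returns None when the stage offers no block of ``block_s`` seconds.
    """
    freqs, specs = None, []
    for lo, hi in mask.merged().intervals:
        i0 = int(round((lo - rec.t0) * rec.rate))
        i1 = int(round((hi - rec.t0) * rec.rate))
        f, s = _welch_blocks(rec.samples[max(i0, 0) : i1], rec.rate, block_s)
        if f is not None:
            freqs = f
            specs.extend(s)
    if not specs:
        return None
    psd = np.mean(specs, axis=0)
    out = {}
    for name, (lo, hi) in bands.items():
        sel = (freqs >= lo) & (freqs <= hi)
        out[name] = float(np.trapezoid(psd[sel], freqs[sel])) if sel.sum() > 1 else 0.0
    out["total"] = float(np.trapezoid(psd, freqs))
    return out
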