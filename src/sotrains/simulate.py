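"""Synthetic full-night generator with exact ground truth.

A synthetic night consists of (1) a hypnogram built from ordered stage blocks
arranged in sleep cycles, (2) a ground-truth SO event table laid down as a
clustered point process, and (3) a rendered EEG trace: each event is a
negative half-sine followed by a positive half-sine added onto 1/f background
noise.

Events are placed stage by stage inside artifact-free S2/SWS epochs.
Trains are constructed explicitly — a train length is drawn from a truncated
geometric distribution, then within-train gaps are drawn uniformly on
[1.0, 2.0] s — rather than emerging from a homogeneous point process, so the
ground-truth isolated/consecutive labels are exact, not probabilistic.
Between-unit gaps are log-normal, truncated below at δ + 0.2 s so that no
between-train gap can be confused with a within-train one. The unit sequence
alternates isolated events and trains at random such that the expected
fraction of events belonging to trains equals ``train_fraction`` and the
realized per-stage density approaches the target.

Waveform draws satisfy the detection criteria by construction: negative
half-wave 0.4–1.2 s, positive half-wave 0.2–0.8 s, trough −110…−45 µV,
trough-to-crest 80–140 µV (with the lower bound raised to |C| + 20 µV so the
positive peak stays positive). Where neighboring waves inside a train would
crowd each other, durations are drawn from correspondingly narrowed ranges.

Rendering is band-limited: each event template is convolved with the SO-band
FIR kernel before insertion, so the drawn trough depth and trough-to-crest
amplitude hold in the band where the detector measures them, with the trough
anchored at the event time. Each wave trails into a shallow rebound (capped
at 45 µV, closed by a ≤14-µV bump) emulating the next down state of an
ongoing oscillation; the rebound keeps the crest from smearing into a
slow positive tail and restores the zero crossings a clean synthetic baseline
would otherwise lack. The rebound's trough-to-crest stays far below the
detector's 75-µV PTP criterion, although on densely clustered nights a small
fraction (~1-3%) can merge with a neighbouring wave's flank and register as
extra detections.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd

from .io import EPOCH_LEN, AnalysisMask, Hypnogram, Recording, analysis_mask, \
    write_edf, write_hypnogram
from .nulls import FeasibilityError

_REB_FLOOR = 35.0  # µV, minimum rebound depth

GT_COLUMNS = ["t", "stage", "epoch", "label", "train_id", "train_len"]


@dataclass(frozen=True)
class SynthParams:
    """Generator settings; defaults describe a young-adult-like night."""

    seed: int = 0
    night_len_h: float = 8.0
    stage_blocks: tuple | None = None        # ((stage, minutes), ...) or None
    density: dict = field(default_factory=lambda: {"S2": 2.2, "SWS": 3.8})
    train_fraction: float = 0.55
    train_q: float = 0.45                    # continue-probability of train length
    train_len_max: int = 12
    within_isoi: tuple[float, float] = (1.0, 2.0)
    between_sigma: float = 0.8               # log-scale spread of between gaps
    d_neg: tuple[float, float] = (0.4, 1.2)
    d_pos: tuple[float, float] = (0.2, 0.8)
    c_range: tuple[float, float] = (-110.0, -45.0)
    ptp_range: tuple[float, float] = (80.0, 140.0)
    noise_rms: float = 10.0                  # µV within the broadband
    noise_alpha: float = 1.0
    rate: float = 100.0
    delta: float = 2.0
    margin: float = 0.2                      # between gaps exceed delta + margin
    edge_margin: float = 1.5                 # clearance from mask-interval edges


def young_like(seed: int = 0, **kw) -> SynthParams:
    """High-density, strongly clustered night (plausibility preset)."""
    return SynthParams(seed=seed, **kw)


def elderly_like(seed: int = 0, **kw) -> SynthParams:
    """Low-density, weakly clustered, more fragmented night (plausibility preset)."""
    kw.setdefault("density", {"S2": 0.8, "SWS": 1.6})
    kw.setdefault("train_fraction", 0.2)
    kw.setdefault("stage_blocks", default_stage_blocks(
        kw.pop("night_len_h", 8.0), sws_scale=0.45, wake_min=6.0))
    return SynthParams(seed=seed, **kw)


def default_stage_blocks(night_len_h: float, sws_scale: float = 1.0,
                         wake_min: float = 2.0) -> tuple:
    """Ordered (stage, minutes) blocks arranged in ~90-min cycles.

    SWS dominates early cycles and REM late ones, the usual overnight
    gradient; ``sws_scale`` shrinks SWS (its minutes go to S2) and
    ``wake_min`` sets the brief awakening at each cycle's end.
    """
    sws_per_cycle = [30.0, 24.0, 16.0, 10.0, 6.0, 4.0]
    rem_per_cycle = [8.0, 12.0, 16.0, 20.0, 24.0, 26.0]
    blocks: list[tuple[str, float]] = [("W", 10.0), ("S1", 5.0)]
    total = 15.0
    target = night_len_h * 60.0
    for cyc in range(len(sws_per_cycle)):
        sws = sws_per_cycle[cyc] * sws_scale
        s2_extra = sws_per_cycle[cyc] - sws
        for stage, mins in [("S2", 22.0 + s2_extra / 2), ("SWS", sws),
                            ("S2", 12.0 + s2_extra / 2),
                            ("REM", rem_per_cycle[cyc]),
                            ("W", wake_min), ("S1", 2.0)]:
            if mins <= 0:
                continue
            mins = min(mins, target - total)
            if mins <= 0:
                break
            blocks.append((stage, mins))
            total += mins
        if total >= target:
            break
    return tuple(blocks)


def _blocks_to_hypnogram(blocks) -> Hypnogram:
    stages: list[str] = []
    for stage, minutes in blocks:
        stages.extend([stage] * int(round(minutes * 2)))
    return Hypnogram(stages=np.array(stages))


def _train_length_pmf(q: float, l_max: int) -> tuple[np.ndarray, np.ndarray]:
    lengths = np.arange(2, l_max + 1)
    w = q ** (lengths - 2)
    return lengths, w / w.sum()


@dataclass
class SynthGroundTruth:
    """Generator-side event table with exact labels and train structure."""

    events: pd.DataFrame
    params: SynthParams

    @property
    def times(self) -> np.ndarray:
        return self.events["t"].to_numpy()


def generate_night(p: SynthParams, rng: np.random.Generator | None = None
                   ) -> tuple[Hypnogram, SynthGroundTruth]:
    """Realize a hypnogram and a ground-truth SO event train for one night."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(p.seed).spawn(1)[0])
    blocks = p.stage_blocks or default_stage_blocks(p.night_len_h)
    h = _blocks_to_hypnogram(blocks)
    mask = analysis_mask(h).merged()

    lengths, pmf = _train_length_pmf(p.train_q, p.train_len_max)
    mean_len = float((lengths * pmf).sum())
    f = p.train_fraction
    p_train = f / (mean_len * (1 - f) + f) if f > 0 else 0.0
    mean_within = float(np.mean(p.within_isoi))
    min_between = p.delta + p.margin

    rows: list[dict] = []
    tid = 0
    for stage, dens in p.density.items():
        if dens <= 0:
            continue
        iv = mask.intervals[mask.stages == stage]
        if iv.size == 0:
            continue
        # mean between-unit gap implied by the target density
        ev_per_unit = p_train * mean_len + (1 - p_train)
        gap_target = 60.0 * ev_per_unit / dens - p_train * (mean_len - 1) * mean_within
        if gap_target <= min_between:
            raise FeasibilityError(
                f"target density {dens}/min in {stage} cannot respect the "
                f"minimum between-train gap of {min_between}s"
            )
        mu_g = np.log(gap_target) - p.between_sigma ** 2 / 2

        def draw_gap() -> float:
            for _ in range(1000):
                g = float(rng.lognormal(mu_g, p.between_sigma))
                if g > min_between:
                    return g
            raise FeasibilityError("between-gap truncation keeps rejecting")

        for lo, hi in iv:
            cursor = lo + p.edge_margin + rng.uniform(0, gap_target / 2)
            while True:
                is_train = rng.random() < p_train
                L = int(rng.choice(lengths, p=pmf)) if is_train else 1
                gaps = rng.uniform(*p.within_isoi, size=L - 1)
                span = float(gaps.sum())
                if cursor + span > hi - p.edge_margin:
                    break
                times = cursor + np.concatenate([[0.0], np.cumsum(gaps)])
                for t in times:
                    rows.append({
                        "t": float(t), "stage": stage,
                        "epoch": int(t // EPOCH_LEN),
                        "label": "consecutive" if L > 1 else "isolated",
                        "train_id": tid if L > 1 else -1,
                        "train_len": L if L > 1 else 0,
                    })
                if L > 1:
                    tid += 1
                cursor = float(times[-1]) + draw_gap()

    events = pd.DataFrame(rows, columns=GT_COLUMNS).sort_values(
        "t", ignore_index=True)
    return h, SynthGroundTruth(events=events, params=p)


def _pink_noise(n: int, rng: np.random.Generator, alpha: float) -> np.ndarray:
    """Unit-RMS 1/f^alpha noise via spectral shaping."""
    white = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n)
    shape = np.zeros_like(f)
    shape[1:] = f[1:] ** (-alpha / 2)
    x = np.fft.irfft(white * shape, n)
    sd = x.std()
    return x / sd if sd > 0 else x


@lru_cache(maxsize=4)
def _so_band_kernel(rate: float, low: float = 0.3, high: float = 1.5) -> np.ndarray:
    """The SO-band FIR kernel (0.2 Hz transitions), as used for detection."""
    import mne

    return np.asarray(mne.filter.create_filter(
        None, sfreq=rate, l_freq=low, h_freq=high,
        l_trans_bandwidth=0.2, h_trans_bandwidth=0.2,
        method="fir", phase="zero", fir_design="firwin", verbose="error"))




def render_signal(h: Hypnogram, gt: SynthGroundTruth,
                  rng: np.random.Generator | None = None) -> Recording:
    """Render the night's EEG: band-limited SO waveforms on 1/f noise (µV).

    Each event's raw template (negative then positive half-sine) is convolved
    with the SO-band kernel before insertion, so the waveform lives entirely
    in the band in which detection measures it: the in-band trough falls at
    the event time and the in-band trough-to-crest amplitude equals the drawn
    PTP, whatever the wave's duration. Raw out-of-band half-sine pulses would
    instead lose up to ~40% of their amplitude to the narrow-band measurement
    and shift their apparent trough, making the generator's amplitude ground
    truth meaningless.
    """
    p = gt.params
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(p.seed).spawn(2)[1])
    rate = p.rate
    n = int(round(h.duration * rate))
    x = (_pink_noise(n, rng, p.noise_alpha) * p.noise_rms
         if p.noise_rms > 0 else np.zeros(n))
    kernel = _so_band_kernel(rate, *_detection_band(p))

    t_ev = gt.times
    prev_tail = -np.inf
    for i, t in enumerate(t_ev):
        gap_next = (t_ev[i + 1] - t) if i + 1 < t_ev.size else np.inf
        head_room = t - prev_tail
        # keep neighbouring main lobes disjoint: reserve d_pos_min of tail
        # here and d_neg_min/2 of head for the next wave
        dneg_hi = min(p.d_neg[1], 2 * head_room,
                      2 * (gap_next - p.d_pos[0] - p.d_neg[0] / 2))
        dneg_hi = max(dneg_hi, p.d_neg[0])  # ranges stay valid by construction
        d_neg = rng.uniform(p.d_neg[0], dneg_hi)
        dpos_hi = min(p.d_pos[1], gap_next - d_neg / 2 - p.d_neg[0] / 2)
        if gap_next - d_neg / 2 > 1.2:
            # too far for the next wave's head to terminate the positive
            # phase within the detector's 1.0-s limit: leave room for a
            # rebound lobe wide enough to survive the 1.5-Hz low-pass
            # (≥0.4 s) plus its 0.5-s ring clearance
            dpos_hi = min(dpos_hi, gap_next - d_neg / 2 - 0.9)
        dpos_hi = max(dpos_hi, p.d_pos[0])
        d_pos = rng.uniform(p.d_pos[0], dpos_hi)
        C = rng.uniform(*p.c_range)
        ptp = rng.uniform(max(p.ptp_range[0], -C + 20.0), p.ptp_range[1])
        D = ptp + C

        n_neg = int(round(d_neg * rate))
        n_pos = int(round(d_pos * rate))
        raw = np.concatenate([
            C * np.sin(np.pi * np.arange(n_neg) / n_neg),
            D * np.sin(np.pi * np.arange(n_pos) / n_pos),
        ])
        # shallow rebound into the next down state: SOs are one cycle of an
        # ongoing oscillation, not an isolated pulse clamped at baseline. The
        # rebound balances the wave's area (so the crest is not smeared into a
        # slow positive tail) and is capped at 35 µV — too shallow to pass the
        # PTP criterion itself. Skipped when the next wave's own negative head
        # already provides the end crossing.
        w = np.convolve(raw, kernel)
        k_tr = int(np.argmin(w))
        crest = w[k_tr:].max()
        # drawn PTP and trough depth are honoured as in-band lower bounds; the
        # trough gets a 12-µV margin so neighbouring waves' filter rings cannot
        # lift a marginal trough back above the detection cutoff
        w *= max(ptp / (crest - w[k_tr]), (C - 12.0) / w[k_tr])
        i0 = int(round(t * rate)) - k_tr
        lo, hi = max(i0, 0), min(i0 + w.size, n)
        if hi > lo:
            x[lo:hi] += w[lo - i0 : hi - i0]
        # rebound into the next down state: forces the end zero crossing of
        # the positive phase when the next wave is too far to do so. Added
        # outside the amplitude scaling at a fixed 35 µV so its in-band trough
        # (~-30 µV) can never pass the -40 µV detection cutoff by itself.
        d_reb = min(1.0, gap_next - d_neg / 2 - d_pos - 0.5)
        if d_reb >= 0.4:
            n_reb = int(round(d_reb * rate))
            in_train = gap_next <= 2.05
            # inside a train the rebound must outweigh the crest's smear and a
            # closing bump must restore the up-crossing ahead of the next
            # wave's head; after an isolated wave a plain shallow lobe is
            # enough. Depths keep the rebound's own trough-to-crest below the
            # 60-uV elderly PTP criterion, so rebounds never register as waves.
            a_reb = 42.0 if in_train else _REB_FLOOR
            parts = [-a_reb * np.sin(np.pi * np.arange(n_reb) / n_reb)]
            if in_train:
                n_bump = int(round(0.3 * rate))
                parts.append(10.0 * np.sin(np.pi * np.arange(n_bump) / n_bump))
            w_reb = np.convolve(np.concatenate(parts), kernel)
            w_reb *= a_reb / max(-w_reb.min(), 1e-9)
            j0 = i0 + raw.size  # rebound starts where the positive lobe ends
            lo, hi = max(j0, 0), min(j0 + w_reb.size, n)
            if hi > lo:
                x[lo:hi] += w_reb[lo - j0 : hi - j0]
        prev_tail = t + d_neg / 2 + d_pos
    return Recording(samples=x, rate=rate, channel="Cz-synthetic")


def _detection_band(p: SynthParams) -> tuple[float, float]:
    return (0.3, 1.5)


def simulate_subject(p: SynthParams) -> tuple[Recording, Hypnogram, SynthGroundTruth]:
    """Full seeded night: hypnogram, ground truth and rendered trace."""
    children = np.random.SeedSequence(p.seed).spawn(2)
    h, gt = generate_night(p, np.random.default_rng(children[0]))
    rec = render_signal(h, gt, np.random.default_rng(children[1]))
    return rec, h, gt


def write_night(outdir: str | Path, rec: Recording, h: Hypnogram,
                gt: SynthGroundTruth, stem: str = "night") -> dict[str, Path]:
    """Serialize a synthetic night as EDF + hypnogram CSV + ground-truth CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "edf": outdir / f"{stem}.edf",
        "hypnogram": outdir / f"{stem}_hypnogram.csv",
        "ground_truth": outdir / f"{stem}_groundtruth.csv",
    }
    write_edf(paths["edf"], rec)
    write_hypnogram(paths["hypnogram"], h)
    gt.events.to_csv(paths["ground_truth"], index=False)
    return paths


def match_events(detected_t: np.ndarray, true_t: np.ndarray,
                 tol: float = 0.5) -> pd.DataFrame:
    """Mutual-nearest matching of detected to true event times.

    A true event and a detection are matched when each is the other's nearest
    counterpart and they lie within ``tol`` seconds; this prevents a missed
    wave from "stealing" the detection of its neighbour. Returns a frame with
    true time, matched detection time (NaN when missed), and the timing error.
    """
    detected_t = np.asarray(detected_t, dtype=float)
    true_t = np.asarray(true_t, dtype=float)
    rows = []
    for t in true_t:
        t_det = np.nan
        if detected_t.size:
            k = int(np.argmin(np.abs(detected_t - t)))
            back = int(np.argmin(np.abs(true_t - detected_t[k])))
            if abs(detected_t[k] - t) <= tol and back == int(np.argmin(np.abs(true_t - t))):
                t_det = detected_t[k]
        rows.append({"t_true": t, "t_det": t_det, "err": t_det - t})
    return pd.DataFrame(rows, columns=["t_true", "t_det", "err"])
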