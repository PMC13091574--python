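"""Reading and writing of polysomnography inputs.

Signals travel as EDF (read through MNE, values converted to µV); hypnograms
as plain CSV in one of two dialects:

* dialect A (``per-epoch``): rows of ``epoch,stage``, one row per 30-s epoch;
* dialect B (``intervals``): rows of ``onset_s,duration_s,stage`` whose
  durations must be multiples of 30 s.

Stage vocabularies from R&K (S1..S4) and AASM (N1..N3) scorings are unified to
``{W, S1, S2, SWS, REM, UNSCORED}`` before any analysis. Time is expressed in
seconds from the start of the recording; epoch ``i`` spans ``[30*i, 30*(i+1))``
(half-open).
"""

from __future__ import annotations

import logging
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

EPOCH_LEN = 30.0

UNIFIED_STAGES = ("W", "S1", "S2", "SWS", "REM", "UNSCORED")

_RK_MAP = {
    "W": "W", "S1": "S1", "S2": "S2", "S3": "SWS", "S4": "SWS",
    "REM": "REM", "R": "REM", "MOVEMENT": "UNSCORED", "UNSCORED": "UNSCORED",
}
_AASM_MAP = {
    "W": "W", "N1": "S1", "N2": "S2", "N3": "SWS",
    "REM": "REM", "R": "REM", "MOVEMENT": "UNSCORED", "UNSCORED": "UNSCORED",
}


class SleepIOError(Exception):
    """Base error for malformed input files."""


class ChannelNotFoundError(SleepIOError):
    pass


class AlignmentError(SleepIOError):
    pass


class UnknownLabelError(SleepIOError):
    pass


@dataclass
class Recording:
    """A uniformly sampled single-channel EEG trace in µV."""

    samples: np.ndarray
    rate: float
    channel: str = "EEG"
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if self.samples.size == 0:
            raise ValueError("recording has no samples")

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.rate


@dataclass
class Hypnogram:
    """Per-30-s-epoch stage labels plus per-epoch artifact flags."""

    stages: np.ndarray
    artifact: np.ndarray | None = None
    epoch_len: float = EPOCH_LEN

    def __post_init__(self) -> None:
        self.stages = np.asarray(self.stages, dtype="<U12")
        if self.artifact is None:
            self.artifact = np.zeros(self.stages.size, dtype=bool)
        self.artifact = np.asarray(self.artifact, dtype=bool)
        if self.artifact.size != self.stages.size:
            raise ValueError("stages and artifact flags differ in length")
        if self.epoch_len != EPOCH_LEN:
            raise ValueError("epoch length must be 30 s")

    @property
    def n_epochs(self) -> int:
        return int(self.stages.size)

    @property
    def duration(self) -> float:
        return self.n_epochs * self.epoch_len

    def is_unified(self) -> bool:
        return bool(np.all(np.isin(self.stages, UNIFIED_STAGES)))

    def stage_minutes(self, stage: str, artifact_free: bool = False) -> float:
        sel = self.stages == stage
        if artifact_free:
            sel &= ~self.artifact
        return float(sel.sum()) * self.epoch_len / 60.0


@dataclass
class AnalysisMask:
    """Artifact-free S2/SWS epochs as half-open [start, end) intervals.

    ``intervals`` is an (n, 2) float array aligned to epoch boundaries;
    ``stages`` labels each interval S2 or SWS.
    """

    intervals: np.ndarray
    stages: np.ndarray = field(default_factory=lambda: np.array([], dtype="<U4"))

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=float).reshape(-1, 2)
        self.stages = np.asarray(self.stages, dtype="<U4")
        if self.stages.size != self.intervals.shape[0]:
            raise ValueError("one stage label per interval required")
        if self.intervals.shape[0] > 1:
            starts = self.intervals[:, 0]
            if np.any(np.diff(starts) <= 0):
                raise ValueError("intervals must be sorted and disjoint")
            if np.any(self.intervals[1:, 0] < self.intervals[:-1, 1]):
                raise ValueError("intervals overlap")

    def __len__(self) -> int:
        return int(self.intervals.shape[0])

    @property
    def total_seconds(self) -> float:
        if len(self) == 0:
            return 0.0
        return float(np.diff(self.intervals, axis=1).sum())

    def stage_seconds(self, stage: str) -> float:
        sel = self.stages == stage
        if not sel.any():
            return 0.0
        return float(np.diff(self.intervals[sel], axis=1).sum())

    def merged(self) -> "AnalysisMask":
        """Merge contiguous same-stage intervals.

        Waves are allowed to straddle an epoch boundary when both abutting
        epochs are artifact-free and of the same stage, so containment tests
        run on the merged intervals.
        """
        if len(self) == 0:
            return AnalysisMask(np.empty((0, 2)), np.array([], dtype="<U4"))
        out_iv: list[list[float]] = []
        out_st: list[str] = []
        for (s, e), st in zip(self.intervals, self.stages):
            if out_iv and out_iv[-1][1] == s and out_st[-1] == st:
                out_iv[-1][1] = e
            else:
                out_iv.append([s, e])
                out_st.append(st)
        return AnalysisMask(np.array(out_iv), np.array(out_st))

    def contains(self, t_start: np.ndarray, t_end: np.ndarray) -> np.ndarray:
        """Index of merged-mask interval fully containing [t_start, t_end], or -1."""
        m = self.merged()
        t_start = np.atleast_1d(np.asarray(t_start, dtype=float))
        t_end = np.atleast_1d(np.asarray(t_end, dtype=float))
        idx = np.full(t_start.shape, -1, dtype=int)
        if len(m) == 0:
            return idx
        pos = np.searchsorted(m.intervals[:, 0], t_start, side="right") - 1
        ok = pos >= 0
        ok &= t_start >= np.where(ok, m.intervals[np.clip(pos, 0, None), 0], np.inf)
        ok &= t_end <= m.intervals[np.clip(pos, 0, None), 1]
        idx[ok] = pos[ok]
        return idx


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def read_edf(path: str | Path, channel: str) -> Recording:
    """Read one channel from an EDF/EDF+ file, returning samples in µV."""
    import mne

    path = Path(path)
    if not path.exists():
        raise SleepIOError(f"no such file: {path}")
    try:
        raw = mne.io.read_raw_edf(path, preload=False, verbose="error")
    except Exception as exc:  # mne raises assorted types on bad headers
        raise SleepIOError(f"unreadable EDF file {path}: {exc}") from exc
    if channel not in raw.ch_names:
        raise ChannelNotFoundError(
            f"channel {channel!r} not in {path.name}; available: {raw.ch_names}"
        )
    raw = mne.io.read_raw_edf(path, include=[channel], preload=True, verbose="error")
    data = raw.get_data(picks=[0])[0] * 1e6  # MNE returns volts
    return Recording(samples=data, rate=float(raw.info["sfreq"]), channel=channel)


def write_edf(path: str | Path, rec: Recording, patient: str = "X", recording_id: str = "X") -> None:
    """Write a single-channel Recording to a plain EDF file.

    Uses 1-s data records; the sampling rate must therefore be an integer.
    The trace is zero-padded to a whole number of records and quantized to
    16 bits over a symmetric physical range spanning the data.
    """
    rate = int(round(rec.rate))
    if abs(rate - rec.rate) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    x = rec.samples
    n_rec = int(np.ceil(x.size / rate))
    padded = np.zeros(n_rec * rate)
    padded[: x.size] = x
    phys = max(1.0, float(np.max(np.abs(padded)))) * 1.0001
    dig_min, dig_max = -32768, 32767
    scale = dig_max / phys
    digital = np.clip(np.round(padded * scale), dig_min, dig_max).astype("<i2")

    def f(s: str, n: int) -> bytes:
        return s.encode("ascii")[:n].ljust(n)

    header = b"".join([
        f("0", 8), f(patient, 80), f(recording_id, 80),
        f("01.01.00", 8), f("00.00.00", 8),
        f(str(256 + 256), 8), f("", 44), f(str(n_rec), 8), f("1", 8), f("1", 4),
    ])
    sig = b"".join([
        f(rec.channel, 16), f("", 80), f("uV", 8),
        f(f"{-phys:.8g}"[:8], 8), f(f"{phys:.8g}"[:8], 8),
        f(str(dig_min), 8), f(str(dig_max), 8), f("", 80),
        f(str(rate), 8), f("", 32),
    ])
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig)
        fh.write(struct.pack(f"<{digital.size}h", *digital.tolist()))


# ---------------------------------------------------------------------------
# Hypnogram files
# ---------------------------------------------------------------------------

def _parse_csv_rows(path: str | Path) -> list[list[str]]:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            rows.append([c.strip() for c in line.split(",")])
    if not rows:
        raise SleepIOError(f"empty hypnogram file: {path}")
    return rows


def read_hypnogram(path: str | Path, dialect: str = "per-epoch") -> Hypnogram:
    """Read a hypnogram CSV in either dialect (labels are *not* unified)."""
    rows = _parse_csv_rows(path)
    # tolerate a header row
    if rows and not rows[0][0].lstrip("-").replace(".", "", 1).isdigit():
        rows = rows[1:]
        if not rows:
            raise SleepIOError(f"hypnogram file {path} has a header but no data")
    if dialect == "per-epoch":
        epochs = [int(r[0]) for r in rows]
        if epochs != list(range(len(epochs))):
            raise AlignmentError("per-epoch hypnogram rows must be 0..n-1 in order")
        stages = [r[1] for r in rows]
    elif dialect == "intervals":
        stages_map: dict[int, str] = {}
        for onset_s, dur_s, stage in (r[:3] for r in rows):
            onset, dur = float(onset_s), float(dur_s)
            if onset % EPOCH_LEN or dur % EPOCH_LEN or dur <= 0:
                raise AlignmentError(
                    f"interval ({onset_s}, {dur_s}) not aligned to 30-s epochs"
                )
            for ep in range(int(onset // EPOCH_LEN), int((onset + dur) // EPOCH_LEN)):
                stages_map[ep] = stage
        n = max(stages_map) + 1
        stages = [stages_map.get(i, "UNSCORED") for i in range(n)]
    else:
        raise ValueError(f"unknown hypnogram dialect {dialect!r}")
    return Hypnogram(stages=np.array(stages))


def write_hypnogram(path: str | Path, h: Hypnogram) -> None:
    """Write dialect-A (``epoch,stage``) CSV."""
    with open(path, "w") as fh:
        fh.write("epoch,stage\n")
        for i, s in enumerate(h.stages):
            fh.write(f"{i},{s}\n")


def read_artifacts(path: str | Path, n_epochs: int) -> np.ndarray:
    """Read the optional ``epoch,flag`` artifact CSV; missing file ⇒ no artifacts."""
    path = Path(path)
    flags = np.zeros(n_epochs, dtype=bool)
    if not path.exists():
        return flags
    for row in _parse_csv_rows(path):
        if not row[0].isdigit():
            continue  # header
        ep = int(row[0])
        if ep < n_epochs:
            flags[ep] = bool(int(row[1]))
    return flags


# ---------------------------------------------------------------------------
# Stage unification and masking
# ---------------------------------------------------------------------------

def unify_stages(h: Hypnogram, scheme: str) -> Hypnogram:
    """Map raw R&K or AASM labels onto the unified vocabulary.

    R&K S3 and S4 are grouped as SWS; AASM N3 maps to SWS; N1/N2 map to
    S1/S2. Movement time becomes UNSCORED.
    """
    table = {"RK": _RK_MAP, "AASM": _AASM_MAP}.get(scheme.upper())
    if table is None:
        raise ValueError(f"unknown scoring scheme {scheme!r}")
    out = []
    for lab in h.stages:
        if lab not in table:
            raise UnknownLabelError(f"label {lab!r} not valid under {scheme} scoring")
        out.append(table[lab])
    return Hypnogram(stages=np.array(out), artifact=h.artifact.copy())


def analysis_mask(h: Hypnogram, lights_off: float | None = None) -> AnalysisMask:
    """Artifact-free S2/SWS epochs at or after lights-off, as timed intervals."""
    if not h.is_unified():
        raise ValueError("hypnogram must be unified before masking")
    t_off = 0.0 if lights_off is None else float(lights_off)
    if t_off >= h.duration:
        logger.warning("lights_off at %.0f s is beyond the recording end", t_off)
        return AnalysisMask(np.empty((0, 2)), np.array([], dtype="<U4"))
    iv, st = [], []
    for i, (stage, bad) in enumerate(zip(h.stages, h.artifact)):
        start = i * h.epoch_len
        if stage in ("S2", "SWS") and not bad and start >= t_off:
            iv.append([start, start + h.epoch_len])
            st.append(stage)
    if not iv:
        return AnalysisMask(np.empty((0, 2)), np.array([], dtype="<U4"))
    return AnalysisMask(np.array(iv), np.array(st))
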