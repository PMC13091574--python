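"""End-to-end orchestration: single-subject runs and group-level pooling.

``run_subject`` executes the full chain for one night — broadband filter →
SO detection → isolated/train classification → δ sweep → density-preserving
shuffle → sleep metrics → band power — and returns (and optionally writes)
the per-subject tables. ``run_group`` pools subjects: per-group ISOI
histograms and log-normal shape fits, KS distribution comparison, group-mean
train-length densities, the subject-level density table with its interaction
regression, and the epoch-based density-matched profile.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import architecture, classification as cls, density, detection, nulls, stats
from .io import (AnalysisMask, Hypnogram, Recording, analysis_mask,
                 read_artifacts, read_edf, read_hypnogram, unify_stages)
from .preprocessing import bandpass_filter

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Inputs and knobs for one subject run."""

    subject: str = "s0"
    group: str = "young"                    # sets ptp_min 75 (young) / 60 (elderly)
    dataset: str = "synthetic"
    edf_path: str | None = None
    channel: str | None = None
    hypnogram_path: str | None = None
    hypnogram_dialect: str = "per-epoch"
    scoring_scheme: str | None = None       # None when labels already unified
    artifact_path: str | None = None
    lights_off: float | None = None
    ptp_min: float | None = None            # explicit override of the group value
    delta: float = cls.DELTA_DEFAULT
    delta_grid: tuple = tuple(cls.DELTA_GRID)
    shuffle_reps: int = 10
    shuffle_min_isoi: float = 0.5
    seed: int = 0
    outdir: str | None = None
    compute_spectra: bool = True

    def detection_params(self) -> detection.DetectionParams:
        if self.ptp_min is not None:
            return detection.DetectionParams(ptp_min=self.ptp_min)
        return detection.DetectionParams.for_group(self.group)


@dataclass
class SubjectResult:
    subject: str
    group: str
    dataset: str
    events: pd.DataFrame                 # labeled event table
    classif: cls.Classification
    summary: dict
    isoi: np.ndarray
    sweep: pd.DataFrame
    randomized: dict
    sleep: dict
    band_power: pd.DataFrame | None
    nrem_minutes: float

    def density_rows(self) -> list[dict]:
        base = {"subject": self.subject, "group": self.group,
                "dataset": self.dataset, "n_events": len(self.events),
                "nrem_minutes": self.nrem_minutes}
        return [
            {**base, "p_consecutive": self.classif.p_consecutive, "source": "observed"},
            {**base, "p_consecutive": self.randomized["p_consecutive"],
             "source": "randomized"},
        ]


def analyze_recording(
    rec: Recording,
    h: Hypnogram,
    cfg: RunConfig,
    prefiltered: bool = False,
) -> SubjectResult:
    """Run the full analysis chain on an in-memory recording + hypnogram."""
    mask = analysis_mask(h, lights_off=cfg.lights_off)
    if not prefiltered:
        rec = bandpass_filter(rec)
    events = detection.detect_sos(rec, mask, cfg.detection_params())
    summary = detection.so_summary(events, h)
    classif = cls.classify_events(events, delta=cfg.delta)
    labeled = cls.attach_labels(events, classif)
    labeled.insert(0, "subject", cfg.subject)
    isoi = cls.compute_isoi(events)
    sweep = cls.delta_sweep(events, np.asarray(cfg.delta_grid))
    if len(events) >= 1:
        randomized = nulls.randomized_metrics(
            events, mask,
            nulls.ShuffleParams(min_isoi=cfg.shuffle_min_isoi,
                                n_reps=cfg.shuffle_reps, seed=cfg.seed),
            delta=cfg.delta)
    else:
        randomized = {"p_isolated": np.nan, "p_consecutive": np.nan,
                      "per_rep": {}, "train_length_density": pd.Series(dtype=float),
                      "isoi_histogram": None, "times": []}
    sleep = architecture.sleep_metrics(h).as_dict()
    bp = None
    if cfg.compute_spectra:
        rows = []
        for stage in ("S2", "SWS"):
            sel = mask.stages == stage
            sub = AnalysisMask(mask.intervals[sel], mask.stages[sel])
            powers = architecture.band_power(rec, sub)
            if powers is not None:
                rows.append({"subject": cfg.subject, "stage": stage, **powers})
        bp = pd.DataFrame(rows) if rows else None
    nrem_minutes = (h.stage_minutes("S2", artifact_free=True)
                    + h.stage_minutes("SWS", artifact_free=True))
    return SubjectResult(subject=cfg.subject, group=cfg.group, dataset=cfg.dataset,
                         events=labeled, classif=classif,
                         summary={**summary, **classif.summary()},
                         isoi=isoi, sweep=sweep, randomized=randomized,
                         sleep=sleep, band_power=bp, nrem_minutes=nrem_minutes)


def run_subject(cfg: RunConfig) -> SubjectResult:
    """File-based subject run; writes tables under ``cfg.outdir`` when set."""
    if cfg.edf_path is None or cfg.hypnogram_path is None:
        raise ValueError("run_subject needs edf_path and hypnogram_path")
    rec = read_edf(cfg.edf_path, cfg.channel or "EEG")
    h = read_hypnogram(cfg.hypnogram_path, dialect=cfg.hypnogram_dialect)
    if cfg.scoring_scheme:
        h = unify_stages(h, cfg.scoring_scheme)
    if cfg.artifact_path:
        h.artifact[:] = read_artifacts(cfg.artifact_path, h.n_epochs)
    res = analyze_recording(rec, h, cfg)
    if cfg.outdir:
        write_subject_outputs(res, cfg)
    return res


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.Series):
        return {str(k): float(v) for k, v in obj.items()}
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if np.isnan(v) else v
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    return obj


def write_subject_outputs(res: SubjectResult, cfg: RunConfig) -> None:
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    res.events.to_csv(out / f"{res.subject}_events.csv", index=False)
    res.sweep.to_csv(out / f"{res.subject}_delta_sweep.csv", index=False)
    if res.band_power is not None:
        res.band_power.to_csv(out / f"{res.subject}_band_power.csv", index=False)
    summary = {
        "subject": res.subject, "group": res.group, "dataset": res.dataset,
        "seed": cfg.seed, "delta": cfg.delta,
        "detection": _jsonable(res.summary),
        "randomized": {
            "p_isolated": _jsonable(res.randomized["p_isolated"]),
            "p_consecutive": _jsonable(res.randomized["p_consecutive"]),
            "per_rep": _jsonable(res.randomized["per_rep"]),
        },
        "sleep": _jsonable(res.sleep),
    }
    with open(out / f"{res.subject}_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)


def run_group(results: list[SubjectResult], seed: int = 0,
              outdir: str | None = None) -> dict:
    """Pooled group-level analyses over per-subject results."""
    groups = sorted({r.group for r in results})
    if not results:
        raise ValueError("no subjects")
    by_group = {g: [r for r in results if r.group == g] for g in groups}
    for g, rs in by_group.items():
        if not rs:
            raise ValueError(f"group {g!r} has no subjects")

    out: dict = {"groups": groups}
    pooled_isoi = {g: np.concatenate([r.isoi for r in rs]) if rs else np.array([])
                   for g, rs in by_group.items()}
    out["isoi_histograms"] = {
        g: cls.mean_isoi_histogram(
            [cls.isoi_histogram(r.isoi) for r in rs if r.isoi.size])
        for g, rs in by_group.items()
    }
    out["lognormal"] = {g: stats.lognormal_shape(pooled_isoi[g])
                        for g in groups if pooled_isoi[g].size}
    out["train_length_density"] = {
        g: cls.mean_train_length_density(
            [cls.train_length_density(r.classif) for r in rs])
        for g, rs in by_group.items()
    }
    out["p_isolated"] = {
        g: float(np.mean([r.classif.p_isolated for r in rs]))
        for g, rs in by_group.items()
    }
    if len(groups) == 2 and all(pooled_isoi[g].size for g in groups):
        a, b = groups
        D, p = stats.ks_two_sample(pooled_isoi[a], pooled_isoi[b])
        out["ks"] = {"D": D, "p": p}
        out["delta_sigma"] = stats.delta_sigma_ci(
            pooled_isoi[a], pooled_isoi[b], seed=seed)

    rows = [row for r in results for row in r.density_rows()]
    table = density.global_density_table(rows)
    out["density_table"] = table
    obs = table[table["source"] == "observed"].copy()
    if len(groups) == 2 and obs["group"].nunique() == 2 and len(obs) >= 4:
        out["ols_observed"] = stats.ols_fit(
            obs, "p_consecutive",
            ["nrem_density", "group", "nrem_density:group"],
            center=["nrem_density"],
            references={"group": "elderly"})
        if table["source"].nunique() == 2 and len(table) >= 8:
            out["ols_full"] = stats.ols_fit(
                table, "p_consecutive",
                ["nrem_density", "group", "source",
                 "nrem_density:group", "nrem_density:source", "group:source",
                 "nrem_density:group:source"],
                center=["nrem_density"],
                references={"group": "elderly", "source": "observed"})

    out["epoch_profile"] = {
        g: density.epoch_density_profile(
            pd.concat([r.events for r in rs], ignore_index=True))
        for g, rs in by_group.items()
    }
    if outdir:
        outp = Path(outdir)
        outp.mkdir(parents=True, exist_ok=True)
        stats.export_for_stats(table, outp / "subject_density_table.csv")
        for g in groups:
            out["epoch_profile"][g].to_csv(
                outp / f"epoch_profile_{g}.csv", index=False)
        prop_rows = [{"subject": r.subject, "group": r.group,
                      "dataset": r.dataset, "source": src,
                      "p_isolated": (r.classif.p_isolated if src == "observed"
                                     else r.randomized["p_isolated"])}
                     for r in results for src in ("observed", "randomized")]
        stats.export_for_stats(pd.DataFrame(prop_rows),
                               outp / "proportions_for_external_stats.csv")
    return out
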