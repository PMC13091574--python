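"""Synthetic cohort construction: the unit the group analyses operate on.

A cohort is a list of per-subject pipeline results, one synthetic night per
subject, built from the young-like and elderly-like presets with per-subject
seeds. The presets differ in SO density, train fraction, SWS share, and
fragmentation — the contrasts the group-level analyses are designed to
resolve — while detection uses the group amplitude thresholds (75/60 µV).
"""

from __future__ import annotations

import pickle
from pathlib import Path

import numpy as np

from .pipeline import RunConfig, SubjectResult, analyze_recording
from .simulate import elderly_like, simulate_subject, young_like

PRESETS = {"young": young_like, "elderly": elderly_like}


def build_subject(group: str, subject: str, seed: int,
                  night_len_h: float = 6.0,
                  compute_spectra: bool = True) -> SubjectResult:
    params = PRESETS[group](seed=seed, night_len_h=night_len_h)
    rec, h, _ = simulate_subject(params)
    cfg = RunConfig(subject=subject, group=group, seed=seed,
                    compute_spectra=compute_spectra)
    return analyze_recording(rec, h, cfg)


def build_cohort(n_per_group: int = 8, night_len_h: float = 6.0,
                 seed: int = 0, compute_spectra: bool = True
                 ) -> list[SubjectResult]:
    """One synthetic night per subject, seeded reproducibly from ``seed``."""
    sub_seeds = np.random.SeedSequence(seed).generate_state(2 * n_per_group)
    results = []
    k = 0
    for group in ("young", "elderly"):
        for i in range(n_per_group):
            results.append(build_subject(
                group, f"{group[0]}{i:02d}", int(sub_seeds[k] % (2 ** 31)),
                night_len_h, compute_spectra))
            k += 1
    return results


def load_or_build_cohort(cache: str | Path, **kw) -> list[SubjectResult]:
    """Pickle-cached cohort for the analysis drivers (cache lives in scratch/)."""
    cache = Path(cache)
    if cache.exists():
        with open(cache, "rb") as fh:
            return pickle.load(fh)
    results = build_cohort(**kw)
    cache.parent.mkdir(parents=True, exist_ok=True)
    with open(cache, "wb") as fh:
        pickle.dump(results, fh)
    return results
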