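"""Shared paths and the cached cohort for the numbered analysis drivers."""

from pathlib import Path

from sotrains.cohort import load_or_build_cohort

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"

COHORT_SEED = 2026
N_PER_GROUP = 8
NIGHT_HOURS = 6.0


def get_cohort():
    return load_or_build_cohort(
        SCRATCH / f"cohort_seed{COHORT_SEED}.pkl",
        n_per_group=N_PER_GROUP, night_len_h=NIGHT_HOURS, seed=COHORT_SEED)
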