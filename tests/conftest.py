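import dataclasses

import numpy as np
import pytest

from sotrains.io import Hypnogram, Recording, analysis_mask
from sotrains.simulate import SynthParams, simulate_subject, young_like


def make_canonical_wave_night(n_waves: int = 20, spacing: float = 12.0,
                              rate: float = 100.0, noise: float = 0.0,
                              seed: int = 0):
    """Sparse night of identical textbook SOs: 0.5-s negative half-sine to
    −80 µV then 0.5-s positive half-sine to +40 µV, 12 s apart in S2.

    Returns (Recording, Hypnogram, true negative-peak times). The trailing
    −10 µV rebound emulates the ongoing oscillation's next down state.
    """
    dur = n_waves * spacing + 60.0
    n_epochs = int(np.ceil(dur / 30.0))
    h = Hypnogram(np.array(["S2"] * n_epochs))
    n = int(n_epochs * 30 * rate)
    rng = np.random.default_rng(seed)
    x = np.zeros(n)
    if noise > 0:
        white = np.fft.rfft(rng.standard_normal(n))
        f = np.fft.rfftfreq(n)
        shape = np.zeros_like(f)
        shape[1:] = f[1:] ** -0.5
        pink = np.fft.irfft(white * shape, n)
        x = pink / pink.std() * noise
    t_true = 30.0 + spacing * np.arange(n_waves)
    for t in t_true:
        i0 = int((t - 0.25) * rate)
        x[i0 : i0 + 50] += -80 * np.sin(np.pi * np.arange(50) / 50)
        x[i0 + 50 : i0 + 100] += 40 * np.sin(np.pi * np.arange(50) / 50)
        x[i0 + 100 : i0 + 200] += -10 * np.sin(np.pi * np.arange(100) / 100)
    return Recording(x, rate), h, t_true


@pytest.fixture(scope="session")
def canonical_night():
    return make_canonical_wave_night()


@pytest.fixture(scope="session")
def young_night():
    """One rendered noise-free young-like night with ground truth."""
    p = dataclasses.replace(young_like(seed=7, night_len_h=4.0), noise_rms=0.0)
    rec, h, gt = simulate_subject(p)
    return rec, h, gt


@pytest.fixture(scope="session")
def young_night_mask(young_night):
    _, h, _ = young_night
    return analysis_mask(h)
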