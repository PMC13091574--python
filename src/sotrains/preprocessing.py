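"""Broadband conditioning of the selected EEG derivation.

A zero-phase FIR band-pass (default 0.3–35 Hz) applied before any detection,
mirroring standard practice for overnight EEG: the high-pass edge removes
drifts and DC, the low-pass removes EMG/line residue above the bands of
interest. Transition bandwidth at the low edge is 0.1 Hz so the 0.3-Hz corner
stays sharp relative to the slow-oscillation band.
"""

from __future__ import annotations

import numpy as np

from .io import Recording


def bandpass_filter(
    rec: Recording,
    low: float = 0.3,
    high: float = 35.0,
    l_trans: float = 0.1,
    h_trans: float | str = "auto",
) -> Recording:
    """Zero-phase FIR band-pass; output has the same length as the input."""
    import mne

    nyq = rec.rate / 2.0
    if not (0 < low < high):
        raise ValueError("need 0 < low < high")
    if high >= nyq:
        raise ValueError(f"high edge {high} Hz is at/above Nyquist ({nyq} Hz)")
    filtered = mne.filter.filter_data(
        rec.samples.astype(float),
        sfreq=rec.rate,
        l_freq=low,
        h_freq=high,
        l_trans_bandwidth=l_trans,
        h_trans_bandwidth=h_trans,
        method="fir",
        phase="zero",
        fir_design="firwin",
        verbose="error",
    )
    return Recording(samples=np.asarray(filtered), rate=rec.rate,
                     channel=rec.channel, t0=rec.t0)
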