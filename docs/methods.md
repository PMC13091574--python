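# Methods

## Scope and model

`sotrains` analyzes the temporal organization of slow oscillations (SOs,
0.5–1 Hz) in full-night NREM sleep EEG. The pipeline is: broadband
conditioning → SO detection by zero-crossing segmentation → classification of
each SO as *isolated* or part of a *train* of consecutive SOs by inter-SO
interval (ISOI) → density-preserving shuffle surrogates and density-matched
controls → group statistics. A synthetic full-night generator with exact
ground truth stands in for polysomnography data, so every stage is testable
without recordings.

### Detection

The trace is band-passed 0.3–35 Hz (zero-phase FIR, 0.1 Hz low-edge
transition), then filtered to the SO band 0.3–1.5 Hz (zero-phase FIR, 0.2 Hz
transitions). A candidate wave runs from a positive-to-negative zero crossing
(`t_start`), through the next negative-to-positive crossing (`t_mid`, the
mid-crossing), to the following positive-to-negative crossing (`t_end`). A
candidate is an SO when the negative phase lasts 0.3–1.5 s, the positive
phase 0.1–1.0 s, the trough is ≤ −40 µV, and trough-to-crest (PTP) amplitude
is ≥ 75 µV (young adults) or ≥ 60 µV (elderly; a fixed study input reflecting
the known age-related amplitude reduction, never inferred from data). All
features (durations A and B, trough C, crest D, PTP, rising slope |C|/B,
frequency 1/A) are measured on the SO-band signal. Events must lie entirely
within artifact-free S2/SWS epochs; contiguous same-stage artifact-free
epochs are merged before the containment test so waves straddling an epoch
boundary are not lost arbitrarily.

### Classification

ISOIs are measured between negative peaks of successive detections, on the
continuous timeline for the NREM-wide analysis (a wake gap of ≥ 30 s can
never satisfy the threshold anyway); stage-specific reruns first restrict
events to the stage. With threshold δ = 2 s (the upper period limit of a
0.5 Hz rhythm), an SO is consecutive when it lies within δ of either
neighbour, isolated otherwise; a tie at exactly δ counts as consecutive (the
boundary must land somewhere and is measure-zero in continuous data). Trains
are maximal runs with successive gaps ≤ δ; lengths are ≥ 2 by construction.
Proportions are reported relative to total detections and train-length
histograms are density-normalized, making subjects with different detection
counts comparable; group curves average per-subject histograms, zero-padded
to the longest observed train. The δ-sensitivity sweep reruns the
classification over δ = 0.5–10 s in 0.25-s steps.

### Density controls

Two controls separate temporal structure from plain abundance:

* **Shuffle surrogate.** Per repetition (10 by default), each stage's
  negative-peak times are redrawn uniformly over that stage's artifact-free
  mask intervals, preserving per-stage counts exactly and enforcing a minimum
  ISOI of 0.5 s (the smallest interval seen in real data) on the global
  timeline by rejection sampling (cap 10⁴ rejections per repetition, after a
  per-stage packing feasibility check). Surrogates carry only times.
* **Epoch-based profile.** Each 30-s NREM epoch is assigned the events whose
  negative peak falls inside it; the per-epoch proportion of isolated events
  uses the *global* labels (an SO can be consecutive with a neighbour in the
  adjacent epoch, so recomputing labels per epoch would redefine the
  statistic). Epochs are pooled across subjects within group and binned by
  their event count; per-bin means get a normal-approximation 95% CI,
  suppressed below 10 epochs.

### Statistics

Pooled within-group ISOI samples feed a two-sample Kolmogorov–Smirnov test
(asymptotic p) and a log-normal shape fit (ML: μ = mean of logs,
σ = population SD of logs). The between-group shape difference Δσ gets a
seeded nonparametric bootstrap percentile CI (B = 1000, resampling within
group; two-sided p as the doubled crossing proportion floored at 1/B — the
CI method is a declared choice, configurable). The density relationship is
fitted by OLS with mean-centered NREM density, dummy-coded group
(reference: elderly) and, in the full model, the observed-vs-randomized
source factor (reference: observed) with all interactions. Beta and
Dirichlet regressions of composite proportions are intentionally out of
scope; `export_for_stats` writes the tidy tables those models need in an
external statistics environment.

## Synthetic nights

The generator emulates exactly the structure the analysis assumes:

* **Hypnogram** from ordered stage blocks in ~90-min cycles, SWS-heavy early
  and REM-heavy late; 30-s epochs.
* **Event placement** stage by stage inside artifact-free S2/SWS epochs.
  Units are either isolated events or trains whose length follows a
  truncated geometric distribution (continue-probability q = 0.45, support
  2–12, mean ≈ 2.9); the unit type probability is solved so the expected
  fraction of events in trains equals `train_fraction`. Within-train ISOIs
  are uniform on [1, 2] s; between-unit gaps are log-normal (σ = 0.8)
  truncated below at δ + 0.2 s, with the location parameter solved from the
  target per-stage density. Ground-truth labels are therefore exact, and a
  0.2-s margin above δ prevents boundary ambiguity in recovery tests.
* **Waveforms.** Negative half-sine (0.4–1.2 s) then positive half-sine
  (0.2–0.8 s); trough −110…−45 µV, PTP 80–140 µV with the floor raised to
  |C| + 20 µV so the crest stays positive. Templates are *band-limited*:
  each is convolved with the same SO-band kernel the detector uses, anchored
  so the in-band trough sits at the event time, and scaled so the drawn PTP
  and trough depth hold as in-band lower bounds (trough margin 12 µV against
  neighbouring filter rings). Raw out-of-band half-sine pulses would lose up
  to ~40% of their amplitude to the SO-band measurement and shift their
  apparent trough, making amplitude ground truth meaningless. Each wave
  trails into a shallow rebound lobe (35–45 µV, closed by a ≤ 10 µV bump
  inside trains), emulating the next down state of an ongoing oscillation.
  Without it, a synthetic baseline at exact zero gives the zero-crossing
  detector no end crossing within its 1.0-s positive-phase limit and recall
  collapses to ~0.55 — a pathology of silent baselines, not of real EEG. The
  rebound's own trough-to-crest stays below the 60-µV elderly criterion, so
  rebounds do not register as waves, although on densely clustered nights a
  small fraction (~1–3%) merge with a neighbouring wave's flank and appear
  as extra detections.
* **Noise**: 1/f (α = 1) background scaled to 10 µV RMS by default.
* **Presets**: `young_like` (S2 2.2, SWS 3.8 waves/min, train fraction 0.55,
  full SWS) and `elderly_like` (S2 0.8, SWS 1.6 waves/min, train fraction
  0.2, 45% of the SWS minutes, longer awakenings). These are plausibility
  presets for contrast tests, not fitted values.

### What the generator does and does not emulate

It reproduces the features the pipeline's logic depends on: stage-gated
event placement, two-regime ISOI structure (within-train vs between-train),
detection-compliant waveforms, per-stage density, and 1/f background. It
does **not** emulate spindles or K-complexes, multi-channel topography,
age-specific waveform morphology, or the empirical ISOI tail shape — so the
log-normal σ *contrast* between the presets is not calibrated to the aging
effect, and passing tests says nothing about effect sizes in real data, only
that the pipeline measures what the generator planted.

### Measured pipeline accuracy on synthetic nights

On default noisy nights (10 µV RMS), detection recall is 0.95–0.98 with
median trough-timing error ~10 ms. Residual misses concentrate inside trains
whose ISOIs approach 2 s, where the detector's ≤ 1.0-s positive-phase
criterion conflicts with the inter-trough spacing in a band-limited signal;
a missed middle event also flips its neighbours to isolated, so recovered
p_consecutive runs ~0.02–0.05 below the generating train fraction at heavy
clustering (train fraction 0.8). Sparse nights of canonical, well-separated
waves are detected with recall 1.0, zero false positives and sample-level
timing.

## Numerical choices and degenerate inputs

* Epoch *i* spans the half-open interval [30 i, 30 (i + 1)); events map to
  epochs by negative-peak time.
* Zero crossings are linearly interpolated between samples; exact zeros
  inherit the previous sign so each transition is unique.
* Welch spectra use 10-s Hann-tapered blocks at 50% overlap (0.1 Hz
  resolution, no zero-padding), blocks drawn only within contiguous
  artifact-free same-stage spans; band power is the trapezoid integral of
  the mean spectrum; overlapping band definitions (alpha 8–13, slow spindle
  9–12 Hz) are reported as-is.
* Empty cases are explicit: < 2 events give an empty ISOI list; zero trains
  give an empty density (flagged); subjects with no artifact-free NREM are
  skipped with a warning; a hypnogram without S2 leaves onset-relative
  metrics flagged rather than guessed.
* The EDF writer uses 1-s records, 16-bit quantization over a symmetric
  range spanning the data (≲ 0.02 µV error on a ±100 µV night), zero-padding
  the last partial second.
* Feasibility errors are raised before sampling when counts cannot be packed
  (shuffle: count × min-ISOI vs stage time; generator: target density vs
  minimum between-gap).

## Known limitations

* Whole epochs are excluded on artifact flags; partial-epoch trimming is not
  supported.
* Recordings are single contiguous files; fragmented nights must be
  concatenated upstream.
* Fixed δ and fixed amplitude thresholds by design; adaptive or
  waveform-informed variants are out of scope.
* The in-train detection bias above means recovered consecutive proportions
  are conservative at high clustering; group *contrasts* are unaffected in
  direction.
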