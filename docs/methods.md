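# Methods

This note documents the models and procedures implemented in `okntrack`,
the assumptions behind them, the tunable parameters, and what the synthetic
validation does and does not demonstrate.

## Problem setting

Optokinetic nystagmus (OKN) is a reflexive sawtooth eye movement evoked by a
drifting stimulus: a slow phase (SP) tracks the stimulus and a quick phase
(QP) resets the eye in the opposite direction. Detecting whether OKN is
present in a short trial is the basis of objective visual-acuity screening.
Commercial gaze trackers can under-resolve low-amplitude, high-frequency OKN
and report false negatives; `okntrack` implements two ways to read eye
displacement directly from the infrared eye-camera video — pupil centroid
tracking and phase-based motion microscopy — plus the downstream OKN
detection, per-eye/two-stage decision logic, and scoring.

## Complex steerable pyramid (filterbank)

Each 192 × 192 grayscale frame is decomposed in the frequency domain by
real, non-negative masks forming a high-pass residual, a low-pass residual,
and `n_scales × n_orientations` oriented band-pass masks (default 5 × 4 =
20 levels). Radial windows are raised cosines in log₂ frequency with
full-octave spacing (transition cutoffs at π·2⁻ˢ); angular windows are the
standard cos^(K−1) lobes restricted to the half-plane |θ − θ_k| < π/2 and
normalised numerically so that the conjugate-pair sum of squared angular
windows is exactly one. Because the oriented masks cover only one of each
conjugate frequency pair, the inverse DFT of a masked spectrum is complex,
`R_l = A_l e^{jφ_l}`, providing local amplitude and phase.

Design choices:

* **Non-decimated.** All sub-bands are kept at full frame resolution so that
  per-pixel spatial phase gradients and the least-squares solve need no
  resampling. Memory is traded for correctness and simplicity.
* **Tiling convention.** At every non-DC sample,
  `hi² + lo² + Σ_l [B_l(ω)² + B_l(−ω)²] = 1` (checked to < 10⁻⁶, achieved at
  machine precision). Under this convention Parseval reads
  `2 Σ_l ‖R_l‖² + ‖hi‖² + ‖lo‖² = ‖frame‖²` for real frames.
* **DC and Nyquist.** DC belongs entirely to the low-pass residual; the
  Nyquist rows/columns fall at radii ≥ π where only the high-pass residual
  is non-zero. Band boundaries are smooth raised cosines, so there is no
  hard-edge tie-breaking.
* **Feasibility.** The finest admissible scale count for an H × W frame is
  `floor(log2(min(H, W))) − 2`, keeping the lowest octave transition above
  the fundamental frequency; requesting more raises a configuration error
  that names the feasible maximum.

## Phase-based displacement (phaseflow)

Motion is encoded by iso-contours of the unwrapped local phase. For each
level the phase at a pixel is unwrapped **in time** (first sample unchanged,
consecutive differences folded into (−π, π]), optionally median filtered
along time (default window 3 samples), and differenced against the fixed
`t = 0` reference: `Δφ_l(x,t) = φ_l(x,t) − φ_l(x,0)`. A first-order
expansion gives, per level, `∇φ_l · d = Δφ_l`; the displacement is the
weighted least-squares solution of the L-row system (L = 20 by default),
which requires at least two levels with independent gradient orientations.

Numerical choices:

* **Spatial gradients** use wrapped one-step phase differences averaged into
  central differences (one-sided at window borders). Spatially adjacent
  pixels are unwrapped independently in time, so only wrapped local
  differences are meaningful; full 2-D phase unwrapping is ill-posed and
  unnecessary here.
* **Weights** default to `A_l(x,t)·A_l(x,0)` (geometric coupling of the
  amplitudes at both times); `A_l(x,t)²` is available as an alternative.
  Amplitude weighting suppresses levels with no texture content at the
  pixel.
* **Sign convention.** `solve_displacement` returns the literal solution of
  `∇φ · d = Δφ`; image content moving by δ produces `Δφ ≈ −∇φ·δ`, so
  `extract_point_trace` negates the solution and reports content motion
  (positive dx = rightward).
* **Singularity handling.** The 2 × 2 normal matrix is accepted only when
  its smallest eigenvalue exceeds `rcond` (10⁻⁸) times the largest.
  `solve_displacement` raises on failure; `extract_point_trace` marks the
  frame's sample missing and continues. No regularisation is added — a
  silent ridge term would bias amplitude recovery.
* **Reference frame** is fixed at `t = 0`, not sliding. Slow drift over an
  8 s trial is tolerated because OKN detection differentiates the trace.
* **Windowed evaluation.** A point trace needs sub-band values only on a
  (neighborhood+2)² pixel window, so the masked spectrum is summed directly
  at those pixels (the raised-cosine masks have sparse support) instead of
  inverse-transforming full frames — a short complex matrix product per
  level, batched over frames. Single precision is the default for this path;
  its phase error (< 10⁻⁶ relative) is far below the displacement noise
  floor and it halves runtime.
* **Measurement point.** Displacement is solved at every pixel of a 5 × 5
  grid centred on the measurement point — placed nasal to the pupil near the
  limbal edge, where the iris/sclera boundary guarantees oriented content —
  and averaged per frame over the pixels that yielded well-conditioned
  solves.

Accuracy on noiseless seeded texture (FFT-shift ground truth): constant
shifts of 1.0, 0.3, 0.05 and 0.01 px are recovered with well under 10 %
relative error (≈ 0.5 % in practice), vertical leakage below 0.05 px, and
doubling a 0.1 px shift doubles the estimate within 5 %. For displacements
of several pixels relative to the reference frame the first-order expansion
degrades (fine-scale levels saturate first): the recovered waveform remains
a clear sawtooth — sufficient for detection — but its amplitude is no longer
calibrated. This matches the method's intended regime (sub-pixel to a few
pixels).

## Centroid pupil tracking (centroid)

Per frame: pixels strictly darker than `intensity_threshold` inside the
region of interest form 8-connected components; each component is closed by
its convex hull (which also fills holes); candidates are filtered by
equivalent diameter `√(4A/π)` within `diameter_range` and circularity
`4πA/P²` ≥ `circularity_min` (perimeter measured on the hull-filled blob);
among candidates within `consistency_radius` (default 15 px) of the last
valid center, the largest area wins. The first valid frame bootstraps the
track (largest filtered candidate) and serves as the displacement origin.
Centers are unweighted binary centers of mass, reported at sub-pixel
precision. Missing frames are never interpolated — the OKN detector handles
gaps. A video whose loss fraction strictly exceeds 30 % is classified "low
data" (the fraction is computed as an integer count ratio so the boundary
case is exact).

## OKN detection (okndetect)

The sawtooth detector operates on any 1-D displacement trace:

1. Each contiguous run of valid samples is smoothed with a Savitzky–Golay
   filter (order 2, window `smoothing_window` seconds scaled to the trace's
   sampling rate, minimum 5 samples).
2. The smoothed series is segmented into monotone velocity-sign runs; runs
   whose net displacement is below `merge_tolerance` (default a quarter of
   the amplitude threshold) are absorbed into their neighbours so
   sample-level noise does not fragment a slow phase.
3. A run in the known stimulus direction followed immediately by an opposite
   run forms a sawtooth candidate (onset, peak, end).
4. Candidates must pass a consistency test — slow phase longer than quick
   phase and quick phase faster than slow phase, the defining property of
   nystagmus — and amplitude/duration/velocity thresholds.

A trial is OKN-present if two sawteeth are consecutive (end-to-onset gap ≤
`consecutive_gap_max`, default 0.2 s) or three or more occur in total.
No-stimulus trials are tested in both directions. Per-eye flags combine by
logical OR; one available eye decides alone; both eyes unavailable is an
error handled upstream by trial exclusion. The two-stage (STEP) methods are
pure multiplexers: the video-based flag is used only when the gaze flag is
negative, which structurally guarantees STEP sensitivity ≥ gaze sensitivity
at the cost of specificity.

Two presets ship with the package and are frozen in the tests: `p` for gaze
traces (degrees, 200 Hz: minimum SP amplitude 0.3°, SP duration 0.15–2 s,
SP speed 0.5–20°/s, QP speed ≥ 4°/s, smoothing 0.08 s) and `p′` for
video-derived traces (pixels: minimum SP amplitude 1.5 px, SP speed
2–120 px/s, QP speed ≥ 15 px/s, smoothing 0.12 s). Both were fixed
empirically on the synthetic generator at its default scale of 6 px/deg and
are exposed in full through `DetectorParams`.

## Scoring (metrics)

Confusion matrices pool per-trial decisions against truth. MCC is the
Pearson correlation of the two binary vectors (verified against an
independent correlation routine to 10⁻¹²); any zero marginal makes it
undefined and it is reported as NaN, never coerced to 0. Sensitivity and
specificity are the usual rates; accuracy is the standard `(tp+tn)/total`.
Pooled (all-trial) scoring is the primary analysis; per-partition tables are
produced for the "main" (≤ 30 % loss) and "retest" (low-data) datasets.

## Synthetic generator (synthgen)

`make_waveform` produces a piecewise-linear sawtooth: SP ramp over 88 % of
the beat period in the stimulus direction, QP reset over the remaining 12 %,
plus Gaussian noise; the number of complete beats in a trial is
⌊duration × frequency⌋ and their (onset, peak, end) times are returned as
ground truth. `make_gaze_trace` emulates the eye-tracker output at 200 Hz;
its `gaze_quality` factor attenuates the waveform before noise, reproducing
the false-negative regime where a tracker under-resolves small beats.

`render_eye_video` composes a dark pupil (radius 17 px) inside a textured
iris (radius 52 px, band-limited isotropic noise saturated at 2σ so texture
never approaches the pupil's intensity range) on a bright background, and
translates the whole eye rigidly by the commanded waveform using exact
spectral shifts (verified by phase-correlation registration to < 0.02 px).
Static occluders composited after the shift reproduce the two classic
failure modes: `eyelash` bars crossing the pupil, and a `shadow` channel
linking the pupil blob to the frame border; both defeat the geometry filters
of threshold-based segmentation on scheduled frames while leaving the nasal
limbal region (the phase measurement point) clear. The occlusion schedule
deterministically marks ⌊T·fraction⌋ evenly spread frames.

`make_trial_set` builds the study structure: each participant views 12
trials cycling through stimulus visibility levels of 0.5, 0.3 and 0.1 logMAR
plus no-stimulus (three repeats each), with direction randomized per trial.
The visibility → response mapping (amplitude 3.0°, 1.8°, 0.9°; presence
probability 1, 1, 0.6; gaze attenuation 1, 1, 0.35) is a synthetic
construction: large stimuli always evoke full-amplitude OKN, the smallest
sometimes fails to evoke it and, when it does, the emulated gaze signal
under-resolves it. Beat frequency is drawn uniformly from 0.8–1.8 Hz. An
optional leading fraction of participants carries occluders on 40 % of
frames, emulating the subset of participants whose videos defeat centroid
tracking.

Default problem sizes: trials last 8 s; eye videos run at 30 Hz (the
generator's configurable lower end; gaze stays at 200 Hz), and the full
synthetic study uses 20 participants × 12 trials × 2 eyes. These sizes were
chosen as the smallest that exercise every pipeline path with stable pooled
metrics.

### What the synthetic study does and does not show

The generator produces rigid, purely horizontal eye motion, stationary
illumination, stylised occluders, and i.i.d. Gaussian noise. Passing tests
therefore demonstrate the internal correctness of the estimators and
decision logic (sub-pixel recovery against an exact oracle, exact loss
accounting, exact decision tables, and the structural STEP-dominance
property) — not performance on real eyes, which add vertical/torsional
motion, pupillometry, specular glints, blinks, head-relative camera motion,
and perspective distortion. Real-data headline figures cannot be reproduced
without the original participant videos.

## Pipeline and interfaces (pipeline, cli)

`run_pipeline` executes, per trial: gaze detection (preset `p`); per-eye
rendering, centroid tracking and phase tracking (preset `p′`; measurement
point = mean tracked pupil center + 46 px nasal offset, falling back to the
frame center when tracking fails entirely); per-eye OR combination; STEP
selection; partition into "main" (no low-data video in the trial) and
"retest"; and pooled per-method scoring. In the retest partition only the
gaze and phase methods report, since centroid tracking failed there by
construction. Everything is deterministic given the study seed (per-trial
and per-eye seeds are spawned from it).

The library API is the primary interface; `examples/` holds narrative
scripts, and a thin `okntrack` CLI (`simulate`, `track-centroid`,
`track-phase`, `detect`, `evaluate`, `run`, `split`) wraps the same
functions for shell use. Videos are exchanged as TIFF stacks or `.npy`
arrays; traces, events, decisions and metric tables are CSV.

## Known limitations

* Radial spacing is full-octave only; half-octave (denser-scale) pyramids
  are not offered.
* Phase-trace amplitudes are uncalibrated for multi-pixel displacements
  (first-order phase expansion); detection is unaffected in the tested
  regime but gain estimation is out of scope.
* The centroid tracker is deliberately simple (no ellipse fitting, glint
  removal, or learned segmentation) and requires per-recording tuning.
* Detector thresholds are empirical presets, not optimised per dataset.
* Only horizontal OKN is modelled; vertical/torsional nystagmus and
  look-vs-stare classification are out of scope.
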