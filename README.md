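# okntrack

Eye-displacement measurement from infrared eye-camera video and automated
detection of optokinetic nystagmus (OKN).

OKN is a reflexive sawtooth eye movement evoked by a drifting stimulus: the
eye smoothly tracks the pattern (slow phase) and snaps back (quick phase).
Because it requires no response from the patient, OKN presence/absence is a
practical basis for objective visual-acuity screening in pre-verbal children
and adults who cannot complete standard tests. Gaze signals from wearable
eye trackers can under-resolve low-amplitude, high-frequency OKN and report
false negatives; this package extracts the displacement signal directly from
the eye-camera video instead, by two independent routes, and runs the full
detection and evaluation chain on either.

Who it is for: vision scientists and eye-tracking engineers who need
sub-pixel eye displacement traces from video, a transparent OKN detector, or
a reproducible synthetic benchmark for one.

## Methods implemented

* **Centroid tracking (C).** Intensity thresholding inside a region of
  interest, convex-hull closing, equivalent-diameter/circularity filtering,
  and largest-consistent-candidate selection; the pupil's binary center of
  mass per frame gives the trace. Videos losing > 30 % of frames are flagged
  "low data".
* **Phase-based motion microscopy (MMIC).** Each frame is decomposed by a
  complex steerable pyramid (default 5 scales × 4 orientations = 20 levels)
  into complex sub-bands `R_l = A_l e^{jφ_l}`. With phase unwrapped in time
  and referenced to `t = 0`, small motion obeys `∇φ_l · d ≈ Δφ_l` per level,
  and the displacement `d = (Δx, Δy)` is the amplitude-weighted
  least-squares solution `d = (AᵀW²A)⁻¹AᵀW²b` across levels — resolving
  displacements down to hundredths of a pixel without tracking any feature.
* **Sawtooth OKN detection.** Savitzky–Golay smoothing, velocity-sign run
  segmentation, slow/quick pairing in the known stimulus direction, and
  amplitude/duration/velocity validation. A trial is positive on ≥ 2
  consecutive or ≥ 3 total sawteeth; no-stimulus trials are tested in both
  directions; per-eye results combine by logical OR; the two-stage STEP
  variants consult the video methods only when the gaze detector reports
  absence.
* **Scoring.** Pooled confusion matrices with Matthews correlation
  coefficient (MCC), sensitivity, specificity, and accuracy.
* **Synthetic generator.** Seeded eye videos (192 × 192 px, textured iris,
  dark pupil, exact spectral sub-pixel motion), gaze traces, occluder
  failure modes (eyelash bars, shadow channels), and full multi-participant
  trial sets with known truth labels.

## Worked example

Measure an exact 0.3 px and 0.01 px shift from video
(`examples/01_subpixel_displacement.py`):

```text
filter bank: 20 oriented levels + 2 residuals
true shift  0.30 px -> estimated  0.29963 px (relative error 0.12%, vertical leakage 0.0013 px)
true shift  0.01 px -> estimated  0.00996 px (relative error 0.43%, vertical leakage 0.0000 px)
```

Detect OKN in a synthetic gaze trace (`examples/03_detect_okn.py`):

```text
trace: 1600 samples at 200 Hz, 8 true beats
stimulus rightward: 8 sawteeth detected, decision=present
  onset 0.00s peak 0.86s end 1.01s amplitude 1.49 deg velocity +1.72 deg/s
  ...
stimulus leftward (wrong direction): 0 sawteeth -> decision=absent
```

The estimator recovers the commanded sub-pixel shifts to a fraction of a
percent, and the detector fires only for sawteeth ramping in the stimulus
direction — the directional selectivity that separates OKN from drift.
`examples/02_centroid_tracking.py` shows pupil tracking and the low-data
rule. `examples/04_full_study.py` runs a small end-to-end study (4
participants, one with occluded videos) and prints the pooled per-method
tables:

```text
main dataset (clean videos):
   method  tp  fp  fn  tn   mcc  sensitivity  specificity  accuracy
        G  18   0   6  12 0.707         0.75          1.0     0.833
        C  24   0   0  12 1.000         1.00          1.0     1.000
     MMIC  24   0   0  12 1.000         1.00          1.0     1.000
   C-STEP  24   0   0  12 1.000         1.00          1.0     1.000
MMIC-STEP  24   0   0  12 1.000         1.00          1.0     1.000

retest dataset (centroid tracking failed):
   method  tp  fp  fn  tn   mcc  sensitivity  specificity  accuracy
        G   6   0   2   4 0.707        0.750          1.0     0.833
     MMIC   7   0   1   4 0.837        0.875          1.0     0.917
MMIC-STEP   8   0   0   4 1.000        1.000          1.0     1.000
```

The emulated gaze tracker misses the low-amplitude trials (sensitivity
0.75), the video-based methods recover them, and on the occluded "retest"
videos — where centroid tracking cannot report at all — the phase method
still detects nearly every beat. That ordering (video methods remediate
gaze false negatives; STEP never less sensitive than gaze) is the behaviour
the toolkit is designed to measure.

A thin CLI wraps the same functions:

```sh
okntrack simulate --participants 2 --out scratch/demo
okntrack track-centroid scratch/demo/P00T00_left.npy --fps 30 --out trace.csv
okntrack detect trace.csv --direction right --preset video
okntrack run --participants 4 --occluder-fraction 0.25 --out scratch/study
```

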