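"""Sawtooth optokinetic-nystagmus detection and trial-level decisions.

An OKN beat is a triangular sawtooth: a slow phase (SP) ramping in the
stimulus direction followed by a quick phase (QP) resetting the eye in the
opposite direction.  Detection proceeds by (i) Savitzky-Golay smoothing and
differentiation of the displacement trace, (ii) segmenting the velocity sign
into monotone runs (absorbing negligible noise runs), (iii) pairing a
stimulus-direction run with the immediately following opposite run, and
(iv) validating each candidate for consistency (SP longer than QP, QP faster
than SP) and against amplitude/duration/velocity thresholds.

A trial contains OKN if two or more sawteeth are consecutive, or if three or
more isolated sawteeth occur.  Trials without an induction stimulus are
tested in both directions.  Per-eye results combine by logical OR, with a
single available eye deciding alone; the two-stage (STEP) methods use the
video result only when the gaze detector reports absence.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .trace import DisplacementTrace

__all__ = [
    "DetectorParams",
    "GAZE_PRESET",
    "VIDEO_PRESET",
    "SawtoothEvent",
    "Flag",
    "TrialDecision",
    "detect_sawteeth",
    "trial_decision",
    "detect_both_directions",
    "detect_trial",
    "combine_eyes",
    "step_combine",
    "events_to_frame",
]


class Flag(str, enum.Enum):
    PRESENT = "present"
    ABSENT = "absent"
    UNAVAILABLE = "unavailable"

    def __bool__(self) -> bool:  # present-ness in OR logic
        return self is Flag.PRESENT


@dataclass(frozen=True)
class DetectorParams:
    """Thresholds of the sawtooth detector, in the trace's units.

    Two presets ship with the package: :data:`GAZE_PRESET` (``p``, degrees,
    200 Hz gaze) and :data:`VIDEO_PRESET` (``p'``, pixels, video-derived
    traces); both were fixed empirically on the synthetic generator.
    """

    min_sp_amplitude: float = 0.3        # trace units
    sp_duration: tuple[float, float] = (0.15, 2.0)   # s
    sp_velocity: tuple[float, float] = (0.5, 20.0)   # units/s (magnitude)
    qp_velocity_min: float = 4.0         # units/s (magnitude)
    smoothing_window: float = 0.08       # s
    consecutive_gap_max: float = 0.2     # s, end-to-onset gap
    noise_run_tolerance: float | None = None  # units; default amplitude/4

    def __post_init__(self) -> None:
        if self.sp_duration[0] <= 0 or self.sp_duration[0] >= self.sp_duration[1]:
            raise ValueError("sp_duration must be an increasing positive pair")
        if self.sp_velocity[0] <= 0 or self.sp_velocity[0] >= self.sp_velocity[1]:
            raise ValueError("sp_velocity must be an increasing positive pair")
        if self.min_sp_amplitude <= 0 or self.qp_velocity_min <= 0:
            raise ValueError("amplitude and velocity thresholds must be positive")

    @property
    def merge_tolerance(self) -> float:
        if self.noise_run_tolerance is not None:
            return self.noise_run_tolerance
        return self.min_sp_amplitude / 4.0


# preset p: Pupil-style gaze in degrees at 200 Hz
GAZE_PRESET = DetectorParams(
    min_sp_amplitude=0.3,
    sp_duration=(0.15, 2.0),
    sp_velocity=(0.5, 20.0),
    qp_velocity_min=4.0,
    smoothing_window=0.08,
)

# preset p': video-derived traces in pixels (centroid or phase), any frame rate
VIDEO_PRESET = DetectorParams(
    min_sp_amplitude=1.5,
    sp_duration=(0.15, 2.0),
    sp_velocity=(2.0, 120.0),
    qp_velocity_min=15.0,
    smoothing_window=0.12,
)


@dataclass(frozen=True)
class SawtoothEvent:
    onset: float
    peak: float
    end: float
    sp_amplitude: float   # magnitude, trace units
    sp_duration: float    # s (= peak - onset)
    sp_velocity: float    # signed, units/s
    direction: int        # +1 rightward slow phase, -1 leftward

    def __post_init__(self) -> None:
        if not self.onset < self.peak < self.end:
            raise ValueError("event must satisfy onset < peak < end")
        if np.sign(self.sp_velocity) != self.direction:
            raise ValueError("sp_velocity sign must match direction")


@dataclass(frozen=True)
class TrialDecision:
    trial: str
    stimulus_direction: str          # left | right | none
    method: str                      # G | C | MMIC | C-STEP | MMIC-STEP
    left: Flag = Flag.UNAVAILABLE
    right: Flag = Flag.UNAVAILABLE
    combined: Flag = Flag.UNAVAILABLE


def _smooth_window_samples(params: DetectorParams, fs: float) -> int:
    w = int(round(params.smoothing_window * fs))
    w = max(w, 5)
    return w + 1 if w % 2 == 0 else w


def _valid_segments(valid: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index ranges of contiguous valid samples."""
    segs = []
    v = np.asarray(valid, dtype=bool)
    idx = np.flatnonzero(np.diff(np.concatenate(([0], v.view(np.int8), [0]))))
    for s, e in zip(idx[::2], idx[1::2]):
        segs.append((int(s), int(e)))
    return segs


def _sign_runs(x: np.ndarray, merge_tol: float) -> list[tuple[int, int, int]]:
    """Monotone runs of a smoothed series as (start, end, sign) index triples.

    Runs whose net displacement is below ``merge_tol`` are absorbed, and
    adjacent same-sign runs re-merged, so that sample-level noise does not
    fragment a slow phase.
    """
    d = np.diff(x)
    if len(d) == 0:
        return []
    signs = np.sign(d).astype(int)
    signs[signs == 0] = 1
    runs = []
    start = 0
    for i in range(1, len(signs)):
        if signs[i] != signs[i - 1]:
            runs.append([start, i, signs[start]])
            start = i
    runs.append([start, len(signs), signs[start]])
    # runs are over diff indices; run [s, e) covers samples s..e inclusive
    changed = True
    while changed and len(runs) > 1:
        changed = False
        keep = []
        i = 0
        while i < len(runs):
            s, e, sg = runs[i]
            disp = abs(x[e] - x[s])
            if disp < merge_tol and 0 < i < len(runs) - 1 and len(runs) >= 3:
                # absorb the blip into the previous run
                keep[-1][1] = e
                changed = True
            elif keep and keep[-1][2] == sg:
                keep[-1][1] = e
                changed = True
            else:
                keep.append([s, e, sg])
            i += 1
        runs = keep
    return [(s, e, sg) for s, e, sg in runs]


def detect_sawteeth(
    trace: DisplacementTrace, stimulus_direction: int, params: DetectorParams
) -> list[SawtoothEvent]:
    """Sawtooth events whose slow phase ramps in ``stimulus_direction``.

    ``stimulus_direction`` is +1 (rightward, increasing displacement) or -1.
    Gaps of missing samples break candidate runs; the trace must contain at
    least one second of valid samples.
    """
    if stimulus_direction not in (+1, -1):
        raise ValueError(
            "stimulus_direction must be +1 or -1; use detect_both_directions "
            "for trials without an induction stimulus"
        )
    fs = trace.sampling_rate
    if np.count_nonzero(trace.valid) < fs:
        raise ValueError("trace must contain at least 1 s of valid samples")
    win = _smooth_window_samples(params, fs)
    events: list[SawtoothEvent] = []
    for s0, s1 in _valid_segments(trace.valid):
        seg = trace.dx[s0:s1]
        tseg = trace.t[s0:s1]
        if len(seg) <= win:
            continue
        smooth = savgol_filter(seg, win, polyorder=2)
        runs = _sign_runs(smooth, params.merge_tolerance)
        for i in range(len(runs) - 1):
            rs, re, sg = runs[i]
            qs, qe, qsg = runs[i + 1]
            if sg != stimulus_direction or qsg == stimulus_direction:
                continue
            sp_amp = abs(smooth[re] - smooth[rs])
            sp_dur = tseg[re] - tseg[rs]
            qp_amp = abs(smooth[qe] - smooth[qs])
            qp_dur = tseg[qe] - tseg[qs]
            if sp_dur <= 0 or qp_dur <= 0:
                continue
            sp_speed = sp_amp / sp_dur
            qp_speed = qp_amp / qp_dur
            # consistency: nystagmus resets are faster and briefer than ramps
            if not (sp_dur > qp_dur and qp_speed > sp_speed):
                continue
            if sp_amp < params.min_sp_amplitude:
                continue
            if not params.sp_duration[0] <= sp_dur <= params.sp_duration[1]:
                continue
            if not params.sp_velocity[0] <= sp_speed <= params.sp_velocity[1]:
                continue
            if qp_speed < params.qp_velocity_min:
                continue
            events.append(
                SawtoothEvent(
                    onset=float(tseg[rs]),
                    peak=float(tseg[re]),
                    end=float(tseg[qe]),
                    sp_amplitude=float(sp_amp),
                    sp_duration=float(sp_dur),
                    sp_velocity=float(stimulus_direction * sp_speed),
                    direction=stimulus_direction,
                )
            )
    return sorted(events, key=lambda e: e.onset)


def trial_decision(
    events: list[SawtoothEvent], params: DetectorParams = GAZE_PRESET
) -> Flag:
    """Present iff >=2 consecutive sawteeth, or >=3 sawteeth in total."""
    if len(events) >= 3:
        return Flag.PRESENT
    for a, b in zip(events, events[1:]):
        if b.onset - a.end <= params.consecutive_gap_max:
            return Flag.PRESENT
    return Flag.ABSENT


def detect_both_directions(
    trace: DisplacementTrace, params: DetectorParams
) -> Flag:
    """Decision for no-stimulus trials: OKN direction is undefined, so both
    directions are tested and either firing counts as present."""
    for direction in (+1, -1):
        events = detect_sawteeth(trace, direction, params)
        if trial_decision(events, params) is Flag.PRESENT:
            return Flag.PRESENT
    return Flag.ABSENT


def detect_trial(
    trace: DisplacementTrace, stimulus_direction: str, params: DetectorParams
) -> Flag:
    """Per-eye trial decision given a named stimulus direction.

    ``stimulus_direction`` is ``"left"``, ``"right"`` or ``"none"``.
    """
    if stimulus_direction == "none":
        return detect_both_directions(trace, params)
    direction = {"right": +1, "left": -1}[stimulus_direction]
    events = detect_sawteeth(trace, direction, params)
    return trial_decision(events, params)


def combine_eyes(left: Flag, right: Flag) -> Flag:
    """Logical OR over available eyes; a single available eye decides alone."""
    avail = [f for f in (left, right) if f is not Flag.UNAVAILABLE]
    if not avail:
        raise ValueError("both eyes unavailable; trial must be excluded upstream")
    return Flag.PRESENT if any(f is Flag.PRESENT for f in avail) else Flag.ABSENT


def step_combine(gaze_flag: Flag, video_flag: Flag) -> Flag:
    """Two-stage selection: the video result is used only on a negative gaze
    result (multiplexer driven by the gaze flag)."""
    if gaze_flag is Flag.PRESENT:
        return Flag.PRESENT
    return video_flag


def events_to_frame(events: list[SawtoothEvent]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "onset_s": e.onset,
                "peak_s": e.peak,
                "end_s": e.end,
                "amplitude": e.sp_amplitude,
                "velocity": e.sp_velocity,
                "direction": e.direction,
            }
            for e in events
        ],
        columns=["onset_s", "peak_s", "end_s", "amplitude", "velocity", "direction"],
    )
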