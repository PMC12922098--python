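import numpy as np
import pytest
from dataclasses import replace

from okntrack.okndetect import (
    DetectorParams,
    Flag,
    GAZE_PRESET,
    SawtoothEvent,
    VIDEO_PRESET,
    combine_eyes,
    detect_both_directions,
    detect_sawteeth,
    detect_trial,
    step_combine,
    trial_decision,
)
from okntrack.synthgen import TrialSpec, make_waveform
from okntrack.trace import DisplacementTrace


def event(onset, amp=1.0, direction=+1, sp_dur=0.6, qp_dur=0.1):
    return SawtoothEvent(
        onset=onset,
        peak=onset + sp_dur,
        end=onset + sp_dur + qp_dur,
        sp_amplitude=amp,
        sp_duration=sp_dur,
        sp_velocity=direction * amp / sp_dur,
        direction=direction,
    )


def noise_trace(seed=0, sd=0.05, duration=8.0, fs=200.0):
    rng = np.random.default_rng(seed)
    t = np.arange(int(duration * fs)) / fs
    return DisplacementTrace(
        t=t, dx=rng.normal(0, sd, len(t)), dy=np.zeros(len(t)),
        valid=np.ones(len(t), bool), units="deg", source="gaze",
    )


def sawtooth_trace(direction="right", amplitude=1.0, freq=1.0, seed=1,
                   sd=0.03, rate=200.0):
    spec = TrialSpec(stimulus_direction=direction, amplitude=amplitude,
                     beat_frequency=freq, noise_sd=sd, seed=seed)
    tr, events = make_waveform(spec, rate=rate)
    return tr, events


# ---------------------------------------------------------------------------
# sawtooth detection
# ---------------------------------------------------------------------------

def test_detects_rightward_sawteeth():
    tr, true_events = sawtooth_trace("right", amplitude=1.0, freq=1.0)
    events = detect_sawteeth(tr, +1, GAZE_PRESET)
    assert len(events) >= len(true_events) - 1
    assert all(e.direction == +1 for e in events)
    assert all(e.onset < e.peak < e.end for e in events)
    # recovered onsets align with ground truth within a smoothing window
    onsets = np.array([e.onset for e in events])
    for t_on, _, _ in true_events[1:-1]:
        assert np.min(np.abs(onsets - t_on)) < 0.15


def test_wrong_direction_rejected():
    tr, _ = sawtooth_trace("right", amplitude=1.0, freq=1.0)
    assert detect_sawteeth(tr, -1, GAZE_PRESET) == []


def test_noise_below_threshold_rejected():
    assert detect_sawteeth(noise_trace(sd=0.05), +1, GAZE_PRESET) == []
    assert detect_sawteeth(noise_trace(sd=0.05), -1, GAZE_PRESET) == []


def test_unknown_direction_errors():
    tr, _ = sawtooth_trace()
    with pytest.raises(ValueError, match="detect_both_directions"):
        detect_sawteeth(tr, 0, GAZE_PRESET)


def test_direction_selectivity_sign_flip():
    """Negating the trace swaps which stimulus direction fires."""
    tr, _ = sawtooth_trace("right", amplitude=1.0, freq=1.2, seed=2)
    flipped = DisplacementTrace(t=tr.t, dx=-tr.dx, dy=tr.dy, valid=tr.valid,
                                units=tr.units, source=tr.source)
    assert len(detect_sawteeth(tr, +1, GAZE_PRESET)) > 0
    assert detect_sawteeth(flipped, +1, GAZE_PRESET) == []
    assert len(detect_sawteeth(flipped, -1, GAZE_PRESET)) > 0


def test_amplitude_scaling_monotonicity():
    """Scaling a detected trace up never reduces the event count."""
    tr, _ = sawtooth_trace("right", amplitude=0.6, freq=1.0, seed=3)
    n1 = len(detect_sawteeth(tr, +1, GAZE_PRESET))
    scaled = DisplacementTrace(t=tr.t, dx=2.5 * tr.dx, dy=tr.dy,
                               valid=tr.valid, units=tr.units, source=tr.source)
    n2 = len(detect_sawteeth(scaled, +1, GAZE_PRESET))
    assert n2 >= n1 > 0


def test_missing_samples_break_runs_without_spurious_events():
    """Invalidating samples inside quick phases must not create slow-phase
    events that span the gaps."""
    tr, true_events = sawtooth_trace("right", amplitude=1.0, freq=1.0, sd=0.01)
    valid = tr.valid.copy()
    for _, peak, end in true_events[::2]:
        i0, i1 = int(peak * 200), int(end * 200)
        valid[i0:i1 + 1] = False
    gappy = DisplacementTrace(t=tr.t, dx=tr.dx, dy=tr.dy, valid=valid,
                              units=tr.units, source=tr.source)
    events = detect_sawteeth(gappy, +1, GAZE_PRESET)
    # every detected slow phase still matches a true ramp
    true_onsets = np.array([e[0] for e in true_events])
    for e in events:
        assert np.min(np.abs(true_onsets - e.onset)) < 0.2


def test_trace_shorter_than_one_second_rejected():
    tr = noise_trace(duration=0.5)
    with pytest.raises(ValueError, match="1 s"):
        detect_sawteeth(tr, +1, GAZE_PRESET)


# ---------------------------------------------------------------------------
# trial decision truth table
# ---------------------------------------------------------------------------

def test_two_consecutive_present():
    e1 = event(0.0)
    e2 = event(e1.end + 0.1)  # gap 0.1 <= 0.2
    assert trial_decision([e1, e2], GAZE_PRESET) is Flag.PRESENT


def test_three_isolated_present():
    events = [event(0.0), event(2.0), event(4.0)]
    assert trial_decision(events, GAZE_PRESET) is Flag.PRESENT


def test_two_isolated_absent():
    events = [event(0.0), event(3.0)]
    assert trial_decision(events, GAZE_PRESET) is Flag.ABSENT


def test_zero_or_one_event_absent():
    assert trial_decision([], GAZE_PRESET) is Flag.ABSENT
    assert trial_decision([event(1.0)], GAZE_PRESET) is Flag.ABSENT


def test_both_directions_no_stimulus():
    assert detect_both_directions(noise_trace(), GAZE_PRESET) is Flag.ABSENT
    left, _ = sawtooth_trace("left", amplitude=1.2, freq=1.0, seed=4)
    assert detect_both_directions(left, GAZE_PRESET) is Flag.PRESENT
    right, _ = sawtooth_trace("right", amplitude=1.2, freq=1.0, seed=4)
    assert detect_both_directions(right, GAZE_PRESET) is Flag.PRESENT


def test_detect_trial_dispatch():
    tr, _ = sawtooth_trace("left", amplitude=1.0, freq=1.0, seed=6)
    assert detect_trial(tr, "left", GAZE_PRESET) is Flag.PRESENT
    assert detect_trial(tr, "right", GAZE_PRESET) is Flag.ABSENT
    assert detect_trial(noise_trace(), "none", GAZE_PRESET) is Flag.ABSENT


# ---------------------------------------------------------------------------
# eye combination and STEP selection
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "left,right,expected",
    [
        (Flag.ABSENT, Flag.PRESENT, Flag.PRESENT),
        (Flag.PRESENT, Flag.ABSENT, Flag.PRESENT),
        (Flag.ABSENT, Flag.ABSENT, Flag.ABSENT),
        (Flag.PRESENT, Flag.PRESENT, Flag.PRESENT),
        (Flag.ABSENT, Flag.UNAVAILABLE, Flag.ABSENT),
        (Flag.UNAVAILABLE, Flag.PRESENT, Flag.PRESENT),
    ],
)
def test_combine_eyes_or_and_single_eye_fallback(left, right, expected):
    assert combine_eyes(left, right) is expected


def test_combine_eyes_both_unavailable_errors():
    with pytest.raises(ValueError):
        combine_eyes(Flag.UNAVAILABLE, Flag.UNAVAILABLE)


@pytest.mark.parametrize(
    "gaze,video,expected",
    [
        (Flag.PRESENT, Flag.ABSENT, Flag.PRESENT),
        (Flag.PRESENT, Flag.PRESENT, Flag.PRESENT),
        (Flag.ABSENT, Flag.PRESENT, Flag.PRESENT),
        (Flag.ABSENT, Flag.ABSENT, Flag.ABSENT),
    ],
)
def test_step_multiplexer(gaze, video, expected):
    assert step_combine(gaze, video) is expected


def test_step_dominates_gaze():
    """STEP output is exactly gaze OR video, hence never less sensitive than
    the gaze method on any trial set."""
    for g in (Flag.PRESENT, Flag.ABSENT):
        for v in (Flag.PRESENT, Flag.ABSENT):
            s = step_combine(g, v)
            assert bool(s) == (bool(g) or bool(v))
            assert bool(s) >= bool(g)


# ---------------------------------------------------------------------------
# parameter validation
# ---------------------------------------------------------------------------

def test_presets_distinct_and_valid():
    assert GAZE_PRESET != VIDEO_PRESET
    assert GAZE_PRESET.sp_duration[0] < GAZE_PRESET.sp_duration[1]


def test_bad_params_rejected():
    with pytest.raises(ValueError):
        DetectorParams(sp_duration=(2.0, 0.15))
    with pytest.raises(ValueError):
        DetectorParams(min_sp_amplitude=-1.0)


def test_event_invariants_enforced():
    with pytest.raises(ValueError):
        SawtoothEvent(onset=1.0, peak=0.5, end=2.0, sp_amplitude=1.0,
                      sp_duration=0.5, sp_velocity=2.0, direction=+1)
    with pytest.raises(ValueError):
        SawtoothEvent(onset=0.0, peak=0.5, end=0.6, sp_amplitude=1.0,
                      sp_duration=0.5, sp_velocity=-2.0, direction=+1)
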