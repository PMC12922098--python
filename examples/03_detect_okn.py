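"""Detect sawtooth OKN in displacement traces and combine decisions.

Generates a gaze-like trace containing OKN beats, runs the sawtooth detector
in the correct and the wrong stimulus direction, shows the trial decision
rules, and demonstrates the per-eye OR and the two-stage (STEP) multiplexer.
"""

from okntrack import (
    Flag,
    GAZE_PRESET,
    TrialSpec,
    combine_eyes,
    detect_sawteeth,
    make_waveform,
    step_combine,
    trial_decision,
)

spec = TrialSpec(stimulus_direction="right", amplitude=1.5,
                 beat_frequency=1.0, noise_sd=0.05, seed=12)
trace, true_events = make_waveform(spec)
print(f"trace: {len(trace)} samples at 200 Hz, {len(true_events)} true beats")

events = detect_sawteeth(trace, stimulus_direction=+1, params=GAZE_PRESET)
print(f"stimulus rightward: {len(events)} sawteeth detected, "
      f"decision={trial_decision(events, GAZE_PRESET).value}")
for e in events[:3]:
    print(f"  onset {e.onset:.2f}s peak {e.peak:.2f}s end {e.end:.2f}s "
          f"amplitude {e.sp_amplitude:.2f} deg velocity {e.sp_velocity:+.2f} deg/s")

wrong = detect_sawteeth(trace, stimulus_direction=-1, params=GAZE_PRESET)
print(f"stimulus leftward (wrong direction): {len(wrong)} sawteeth -> "
      f"decision={trial_decision(wrong, GAZE_PRESET).value}")

# decision combination: one eye positive is enough; STEP falls back to the
# video method only when the gaze method reported absence
print("eye OR     (absent, present) ->",
      combine_eyes(Flag.ABSENT, Flag.PRESENT).value)
print("eye OR     (absent, unavailable) ->",
      combine_eyes(Flag.ABSENT, Flag.UNAVAILABLE).value)
print("STEP mux   (gaze=absent, video=present) ->",
      step_combine(Flag.ABSENT, Flag.PRESENT).value)
print("STEP mux   (gaze=present, video=absent) ->",
      step_combine(Flag.PRESENT, Flag.ABSENT).value)
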