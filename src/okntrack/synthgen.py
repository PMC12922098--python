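"""Seeded synthetic eye-camera videos, gaze traces, and trial sets.

The generator emulates the statistical structure the measurement pipeline
assumes: an 8 s trial of a horizontally drifting induction stimulus elicits
sawtooth eye displacement — a slow phase (SP) tracking the stimulus at a few
degrees per second and a quick phase (QP) resetting the eye — at beat
frequencies around 0.8-1.8 Hz and amplitudes from ~1 to ~4 degrees.  Eye
videos are 192 x 192 px per eye: a dark pupil inside a textured iris on a
bright sclera, translated rigidly with exact sub-pixel (spectral) shifts.
Optional occluders reproduce the classic failure modes of threshold-based
pupil tracking: eyelash bars crossing the pupil, and shadow "channels"
linking the pupil blob to the dark background.

The visibility -> response mapping (stimulus size in logMAR to OKN amplitude
and presence probability) is synthetic by construction and makes no claim of
modeling human psychometrics; it exists so the pipeline can be exercised on
trials with full, partial, and absent responses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .trace import DisplacementTrace

__all__ = [
    "TrialSpec",
    "TrialRecord",
    "EyeAppearance",
    "make_waveform",
    "make_gaze_trace",
    "render_eye_video",
    "side_by_side",
    "make_trial_set",
    "occlusion_schedule",
]

QP_FRACTION = 0.12  # quick-phase share of a beat period


@dataclass(frozen=True)
class TrialSpec:
    """One trial's ground-truth generating parameters (angles in degrees)."""

    duration: float = 8.0
    stimulus_direction: str = "right"      # left | right | none
    okn_present: bool = True
    amplitude: float = 3.0                 # deg, sawtooth peak-to-trough
    beat_frequency: float = 1.0            # Hz
    noise_sd: float = 0.05                 # deg, additive gaze/trace noise
    gaze_quality: float = 1.0              # gaze amplitude attenuation in [0,1]
    occluder: str = "none"                 # none | eyelash | shadow
    occluded_fraction: float = 0.0         # fraction of frames occluded
    frame_rate: float = 30.0               # eye-video Hz
    gaze_rate: float = 200.0               # eye-tracker Hz
    px_per_deg: float = 6.0                # video scale
    pixel_noise_sd: float = 2.0            # grayscale units
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.okn_present and self.stimulus_direction not in ("left", "right"):
            raise ValueError(
                "okn_present requires stimulus_direction 'left' or 'right'"
            )

    @property
    def direction_sign(self) -> int:
        return {"left": -1, "right": +1, "none": 0}[self.stimulus_direction]


@dataclass(frozen=True)
class EyeAppearance:
    """Rendering geometry and grayscale levels of the synthetic eye."""

    frame_shape: tuple[int, int] = (192, 192)
    iris_radius: float = 52.0
    pupil_radius: float = 17.0
    background_level: float = 205.0
    iris_level: float = 120.0
    pupil_level: float = 22.0
    texture_contrast: float = 32.0
    edge_width: float = 2.0


def _clean_waveform(spec: TrialSpec, t: np.ndarray):
    """Noise-free sawtooth displacement (deg) and its complete-beat events."""
    if not spec.okn_present:
        return np.zeros_like(t), []
    period = 1.0 / spec.beat_frequency
    sp_dur = (1.0 - QP_FRACTION) * period
    n_complete = int(np.floor(spec.duration * spec.beat_frequency + 1e-9))
    sign = spec.direction_sign
    # breakpoints of the piecewise-linear sawtooth, extended one beat past the end
    knots_t, knots_x = [0.0], [0.0]
    k = 0
    while k * period < spec.duration + period:
        knots_t += [k * period + sp_dur, (k + 1) * period]
        knots_x += [sign * spec.amplitude, 0.0]
        k += 1
    x = np.interp(t, knots_t, knots_x)
    events = [
        (k * period, k * period + sp_dur, (k + 1) * period)
        for k in range(n_complete)
    ]
    return x, events


def make_waveform(spec: TrialSpec, rate: float | None = None):
    """Ground-truth displacement trace in degrees plus true (onset, peak, end)
    event times of every complete sawtooth.

    ``okn_present=False`` yields zero-mean noise.  Identical specs (and seed)
    produce bit-identical arrays.
    """
    rate = spec.gaze_rate if rate is None else rate
    t = np.arange(int(round(spec.duration * rate))) / rate
    x, events = _clean_waveform(spec, t)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 11]))
        x = x + rng.normal(0.0, spec.noise_sd, size=t.shape)
    trace = DisplacementTrace(
        t=t,
        dx=x,
        dy=np.zeros_like(x),
        valid=np.ones(len(t), dtype=bool),
        units="deg",
        source="synthetic",
        meta={"seed": spec.seed, "okn_present": spec.okn_present},
    )
    return trace, events


def make_gaze_trace(spec: TrialSpec) -> DisplacementTrace:
    """Emulated eye-tracker gaze at 200 Hz, in degrees.

    ``gaze_quality`` scales the OKN waveform before noise is added, emulating
    an eye-tracker that under-resolves low-amplitude beats (the false-negative
    regime the video methods are meant to remediate).
    """
    t = np.arange(int(round(spec.duration * spec.gaze_rate))) / spec.gaze_rate
    x, _ = _clean_waveform(spec, t)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 13]))
    x = spec.gaze_quality * x + rng.normal(0.0, spec.noise_sd, size=t.shape)
    return DisplacementTrace(
        t=t,
        dx=x,
        dy=np.zeros_like(x),
        valid=np.ones(len(t), dtype=bool),
        units="deg",
        source="gaze",
        meta={"seed": spec.seed, "gaze_quality": spec.gaze_quality},
    )


def occlusion_schedule(n_frames: int, fraction: float) -> np.ndarray:
    """Deterministic boolean schedule occluding exactly floor(n*fraction)
    frames, spread evenly through the video."""
    k = np.arange(n_frames)
    return np.floor((k + 1) * fraction) > np.floor(k * fraction)


def _smoothstep(d: np.ndarray, width: float) -> np.ndarray:
    """0 -> 1 transition over ``width`` px as signed distance crosses zero."""
    s = np.clip(d / width + 0.5, 0.0, 1.0)
    return s * s * (3 - 2 * s)


def _base_eye_image(appearance: EyeAppearance, rng: np.random.Generator):
    """Static eye image (float64) centred in the frame, constant at borders."""
    H, W = appearance.frame_shape
    cy, cx = (H - 1) / 2.0, (W - 1) / 2.0
    yy, xx = np.mgrid[0:H, 0:W]
    r = np.hypot(xx - cx, yy - cy)
    a = appearance
    iris_in = 1.0 - _smoothstep(r - a.iris_radius, a.edge_width)
    pupil_in = 1.0 - _smoothstep(r - a.pupil_radius, a.edge_width)
    img = a.background_level + (a.iris_level - a.background_level) * iris_in
    img = img + (a.pupil_level - a.iris_level) * pupil_in
    # band-limited isotropic texture confined to the iris annulus; guarantees
    # oriented spectral content at the limbal measurement region.  Saturated
    # at 2 sigma so texture never dips near the pupil's intensity range.
    tex = gaussian_filter(rng.normal(size=(H, W)), 1.2)
    tex = np.clip(tex / max(tex.std(), 1e-12), -2.0, 2.0) * a.texture_contrast / 2.0
    annulus = iris_in * (1.0 - pupil_in)
    img = img + tex * annulus
    return img, (cx, cy)


def _spectral_shift_stack(image: np.ndarray, dx: np.ndarray) -> np.ndarray:
    """Translate ``image`` horizontally by each ``dx`` (exact spectral shift).

    Horizontal-only motion needs the transform along x alone, so frames share
    the row-wise spectrum and only a 1-D inverse per frame is required.
    """
    W = image.shape[1]
    wx = 2 * np.pi * np.fft.fftfreq(W)
    spec = np.fft.fft(image.astype(np.float32), axis=1).astype(np.complex64)
    ramps = np.exp(-1j * np.outer(dx, wx)).astype(np.complex64)  # (T, W)
    shifted = np.fft.ifft(spec[None, :, :] * ramps[:, None, :], axis=2).real
    return shifted.astype(np.float32)


def _apply_occluder(video: np.ndarray, schedule: np.ndarray, kind: str,
                    center: tuple[float, float], appearance: EyeAppearance) -> None:
    """Draw static occluders in-place on the scheduled frames.

    Eyelash bars cross the pupil from above; the shadow channel is a dark
    band linking the pupil to the lower frame border.  Both are kept clear of
    the nasal limbal region where the phase measurement point sits.
    """
    H, W = video.shape[1:]
    cx, cy = center
    occ = np.zeros((H, W), dtype=bool)
    if kind == "eyelash":
        top = max(int(cy - appearance.iris_radius - 12), 0)
        bottom = int(cy + appearance.pupil_radius * 0.6)
        for off in (-18, -8, 2, 12):
            x0 = int(cx + off)
            occ[top:bottom, x0:x0 + 3] = True
        level = 12.0
    elif kind == "shadow":
        x0 = int(cx - 8)
        occ[int(cy):H, x0:x0 + 15] = True
        level = 28.0
    else:
        raise ValueError(f"unknown occluder kind {kind!r}")
    for k in np.flatnonzero(schedule):
        video[k][occ] = level


def render_eye_video(
    spec: TrialSpec,
    waveform_px: np.ndarray,
    appearance: EyeAppearance = EyeAppearance(),
    eye: str = "left",
) -> np.ndarray:
    """Render one eye's (T, H, W) float32 video for a horizontal waveform.

    ``waveform_px`` is the per-frame horizontal displacement of the eye in
    pixels (positive = rightward).  The pupil-iris assembly translates
    rigidly with exact sub-pixel interpolation; occluders (if scheduled) and
    pixel noise are composited afterwards and do not move.
    """
    waveform_px = np.asarray(waveform_px, dtype=float)
    H, W = appearance.frame_shape
    margin = 8.0
    max_shift = float(np.max(np.abs(waveform_px))) if len(waveform_px) else 0.0
    if max_shift + appearance.iris_radius + margin > min(H, W) / 2.0:
        raise ValueError(
            f"waveform amplitude {max_shift:.1f} px would push the iris outside "
            f"the {H}x{W} frame"
        )
    ss = np.random.SeedSequence([spec.seed, 17, 0 if eye == "left" else 1])
    rng_tex, rng_noise = [np.random.default_rng(s) for s in ss.spawn(2)]
    base, center = _base_eye_image(appearance, rng_tex)
    video = _spectral_shift_stack(base, waveform_px).astype(np.float32)
    if spec.occluder != "none" and spec.occluded_fraction > 0:
        sched = occlusion_schedule(len(waveform_px), spec.occluded_fraction)
        _apply_occluder(video, sched, spec.occluder, center, appearance)
    if spec.pixel_noise_sd > 0:
        video += rng_noise.normal(
            0.0, spec.pixel_noise_sd, size=video.shape
        ).astype(np.float32)
    np.clip(video, 0.0, 255.0, out=video)
    return video


def side_by_side(left: np.ndarray, right: np.ndarray) -> np.ndarray:
    """Concatenate per-eye videos into two-eye frames (left half = left eye)."""
    if left.shape != right.shape:
        raise ValueError("left and right videos must share shape")
    return np.concatenate([left, right], axis=2)


# --------------------------------------------------------------------------
# Trial sets
# --------------------------------------------------------------------------

# stimulus size (logMAR) -> (OKN amplitude deg, presence probability,
# gaze attenuation).  None = no-stimulus trial.
VISIBILITY_RESPONSE = {
    0.5: (3.0, 1.0, 1.0),
    0.3: (1.8, 1.0, 1.0),
    0.1: (0.9, 0.6, 0.35),
    None: (0.0, 0.0, 1.0),
}

DEFAULT_VISIBILITY_LEVELS = (0.5, 0.3, 0.1, None)


@dataclass(frozen=True)
class TrialRecord:
    participant: int
    trial: int
    visibility: float | None
    spec: TrialSpec

    @property
    def trial_id(self) -> str:
        return f"P{self.participant:02d}T{self.trial:02d}"

    @property
    def okn_present(self) -> bool:
        return self.spec.okn_present


def make_trial_set(
    n_participants: int,
    trials_per_participant: int = 12,
    visibility_levels=DEFAULT_VISIBILITY_LEVELS,
    seed: int = 0,
    occluder_participant_fraction: float = 0.0,
    frame_rate: float = 30.0,
    px_per_deg: float = 6.0,
) -> list[TrialRecord]:
    """Seeded trial collection with known truth labels.

    Each participant views ``trials_per_participant`` trials cycling through
    the visibility levels (3 repeats of each with the default 12-trial
    protocol); stimulus direction is randomized per trial.  A leading
    fraction of participants receives static occluders on their videos (40 %
    of frames), emulating eyelash/shadow failures of centroid tracking.
    """
    if n_participants < 1 or trials_per_participant < 1:
        raise ValueError("counts must be >= 1")
    root = np.random.SeedSequence(seed)
    part_seqs = root.spawn(n_participants)
    n_occluded = int(round(occluder_participant_fraction * n_participants))
    records: list[TrialRecord] = []
    for p, pseq in enumerate(part_seqs):
        rng = np.random.default_rng(pseq)
        occluded = p < n_occluded
        occ_kind = "eyelash" if p % 2 == 0 else "shadow"
        for t in range(trials_per_participant):
            vis = visibility_levels[t % len(visibility_levels)]
            amp, p_present, gq = VISIBILITY_RESPONSE[vis]
            direction = "left" if rng.random() < 0.5 else "right"
            present = bool(vis is not None and rng.random() < p_present)
            spec = TrialSpec(
                duration=8.0,
                stimulus_direction=direction if vis is not None else "none",
                okn_present=present,
                amplitude=amp,
                beat_frequency=float(rng.uniform(0.8, 1.8)),
                noise_sd=0.05,
                gaze_quality=gq if present else 1.0,
                occluder=occ_kind if occluded else "none",
                occluded_fraction=0.4 if occluded else 0.0,
                frame_rate=frame_rate,
                px_per_deg=px_per_deg,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            records.append(
                TrialRecord(participant=p, trial=t, visibility=vis, spec=spec)
            )
    return records
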