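"""Pupil centroid tracking.

Frames are thresholded inside a region of interest; dark connected
components are closed by convex hull, filtered by equivalent diameter and
circularity, and the largest candidate consistent with the running track is
taken as the pupil.  The displacement trace is the binary center of mass
relative to the first valid frame; frames with no acceptable candidate are
marked missing, and a video losing more than 30 % of its frames is flagged
"low data".

Coordinates are 0-based with x rightward (columns) and y downward (rows);
centers are sub-pixel (unweighted binary center of mass).  Circularity is
``4*pi*area / perimeter**2`` with the perimeter measured on the hull-filled
blob.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi
from skimage.measure import perimeter as _sk_perimeter
from skimage.morphology import convex_hull_image

from .trace import DisplacementTrace

__all__ = [
    "TrackerConfig",
    "PupilEstimate",
    "Candidate",
    "CentroidResult",
    "segment_candidates",
    "select_pupil",
    "track_video",
    "LOW_DATA_LOSS_THRESHOLD",
]

# strict ">30% data loss" rule for the low-data classification
LOW_DATA_LOSS_THRESHOLD = 0.30

_EIGHT = np.ones((3, 3), dtype=int)


@dataclass(frozen=True)
class TrackerConfig:
    """Per-participant tuning of the pupil tracker.

    roi
        (x0, y0, x1, y1) in pixels, 0-based half-open; None = whole frame.
    intensity_threshold
        Pixels strictly darker than this grayscale level are pupil candidates.
    diameter_range
        Acceptable (min, max) equivalent diameter in px, inclusive.
    circularity_min
        Minimum 4*pi*A/P^2 of the hull-closed blob.
    consistency_radius
        Maximum jump of the center from the last valid estimate, px.
    """

    roi: tuple[int, int, int, int] | None = None
    intensity_threshold: float = 70.0
    diameter_range: tuple[float, float] = (10.0, 60.0)
    circularity_min: float = 0.75
    consistency_radius: float = 15.0

    def __post_init__(self) -> None:
        lo, hi = self.diameter_range
        if not lo < hi:
            raise ValueError("diameter_range must satisfy min < max")
        if not 0.0 <= self.circularity_min <= 1.0:
            raise ValueError("circularity_min must lie in [0, 1]")

    def roi_slices(self, frame_shape: tuple[int, int]) -> tuple[slice, slice, int, int]:
        if self.roi is None:
            return slice(0, frame_shape[0]), slice(0, frame_shape[1]), 0, 0
        x0, y0, x1, y1 = self.roi
        if not (0 <= x0 < x1 <= frame_shape[1] and 0 <= y0 < y1 <= frame_shape[0]):
            raise ValueError(f"roi {self.roi} outside frame bounds {frame_shape}")
        return slice(y0, y1), slice(x0, x1), x0, y0


@dataclass(frozen=True)
class Candidate:
    """A hull-closed dark blob with its geometry."""

    center: tuple[float, float]  # (x, y) px, full-frame coordinates
    area: float
    perimeter: float
    equivalent_diameter: float
    circularity: float


@dataclass(frozen=True)
class PupilEstimate:
    frame_index: int
    valid: bool
    center: tuple[float, float] | None = None
    equivalent_diameter: float | None = None
    circularity: float | None = None

    @classmethod
    def missing(cls, frame_index: int) -> "PupilEstimate":
        return cls(frame_index=frame_index, valid=False)


def segment_candidates(frame: np.ndarray, config: TrackerConfig) -> list[Candidate]:
    """Hull-closed dark blobs inside the ROI passing the geometry filters."""
    frame = np.asarray(frame)
    if frame.ndim != 2:
        raise ValueError("frame must be a 2-D grayscale array")
    ys, xs, x_off, y_off = config.roi_slices(frame.shape)
    binary = frame[ys, xs] < config.intensity_threshold
    labels, n = ndi.label(binary, structure=_EIGHT)
    if n == 0:
        return []
    d_lo, d_hi = config.diameter_range
    max_area = np.pi / 4.0 * d_hi**2
    out: list[Candidate] = []
    objects = ndi.find_objects(labels)
    for lab, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        comp = labels[sl] == lab
        if comp.sum() > max_area:
            continue  # hull only grows area, so the diameter filter must fail
        filled = convex_hull_image(comp) if comp.sum() > 2 else comp
        area = float(filled.sum())
        if area <= 0:
            continue
        per = float(_sk_perimeter(filled, neighborhood=4))
        eq_diam = float(np.sqrt(4.0 * area / np.pi))
        circ = 4.0 * np.pi * area / per**2 if per > 0 else 0.0
        if not (d_lo <= eq_diam <= d_hi and circ >= config.circularity_min):
            continue
        cy, cx = ndi.center_of_mass(filled)
        out.append(
            Candidate(
                center=(cx + sl[1].start + x_off, cy + sl[0].start + y_off),
                area=area,
                perimeter=per,
                equivalent_diameter=eq_diam,
                circularity=float(circ),
            )
        )
    return out


def select_pupil(
    candidates: list[Candidate],
    previous_estimate: PupilEstimate | None,
    config: TrackerConfig,
    frame_index: int = 0,
) -> PupilEstimate:
    """Largest candidate consistent with the last valid center.

    With no history (first frame), the largest filtered candidate wins; with
    history, only candidates within ``consistency_radius`` of the previous
    valid center are eligible.  No eligible candidate -> missing.
    """
    eligible = candidates
    if previous_estimate is not None and previous_estimate.valid:
        px, py = previous_estimate.center
        eligible = [
            c
            for c in candidates
            if np.hypot(c.center[0] - px, c.center[1] - py)
            <= config.consistency_radius
        ]
    if not eligible:
        return PupilEstimate.missing(frame_index)
    best = max(eligible, key=lambda c: c.area)
    return PupilEstimate(
        frame_index=frame_index,
        valid=True,
        center=best.center,
        equivalent_diameter=best.equivalent_diameter,
        circularity=best.circularity,
    )


@dataclass
class CentroidResult:
    trace: DisplacementTrace
    loss_fraction: float
    low_data: bool
    estimates: list[PupilEstimate] = field(repr=False, default_factory=list)

    @property
    def mean_center(self) -> tuple[float, float] | None:
        pts = [e.center for e in self.estimates if e.valid]
        if not pts:
            return None
        arr = np.asarray(pts)
        return float(arr[:, 0].mean()), float(arr[:, 1].mean())


def track_video(
    video: np.ndarray, config: TrackerConfig, fps: float = 1.0
) -> CentroidResult:
    """Track the pupil through a (T, H, W) video.

    Displacement is relative to the first valid frame's center; missing
    frames are invalid samples.  ``low_data`` is true iff the loss fraction
    strictly exceeds 30 %.
    """
    video = np.asarray(video)
    if video.ndim != 3 or video.shape[0] < 2:
        raise ValueError("video must be (T, H, W) with at least 2 frames")
    T = video.shape[0]
    estimates: list[PupilEstimate] = []
    last_valid: PupilEstimate | None = None
    for k in range(T):
        cands = segment_candidates(video[k], config)
        est = select_pupil(cands, last_valid, config, frame_index=k)
        estimates.append(est)
        if est.valid:
            last_valid = est
    valid = np.array([e.valid for e in estimates])
    dx = np.full(T, np.nan)
    dy = np.full(T, np.nan)
    if valid.any():
        ref = estimates[int(np.argmax(valid))].center
        for k, e in enumerate(estimates):
            if e.valid:
                dx[k] = e.center[0] - ref[0]
                dy[k] = e.center[1] - ref[1]
    # count invalid frames directly so the strict >30% rule is exact
    loss = (T - int(valid.sum())) / T
    trace = DisplacementTrace(
        t=np.arange(T, dtype=float) / fps,
        dx=dx,
        dy=dy,
        valid=valid,
        units="px",
        source="centroid",
        meta={"intensity_threshold": config.intensity_threshold},
    )
    return CentroidResult(
        trace=trace,
        loss_fraction=float(loss),
        low_data=bool(loss > LOW_DATA_LOSS_THRESHOLD),
        estimates=estimates,
    )
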