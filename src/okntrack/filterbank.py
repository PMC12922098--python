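"""Complex steerable pyramid (CSP) filter bank.

The bank partitions the 2-D discrete Fourier plane into a high-pass residual,
a low-pass residual, and ``n_scales * n_orientations`` oriented band-pass
masks.  Radial windows are raised cosines in log2-frequency with full-octave
spacing; angular windows are the standard ``cos^(K-1)`` lobes restricted to a
half-plane around each orientation.  Because each oriented mask covers only
one of the two conjugate half-planes, the inverse transform of a masked
spectrum is a *complex* image whose argument is a local phase signal — the
quantity the motion microscope differentiates to read out displacement.

Conventions
-----------
* Masks are real and non-negative, shaped like ``numpy.fft.fft2`` output.
* Orientations ``theta_k = pi * k / K`` for ``k = 0..K-1``; orientation 0
  selects vertically-oriented structure moving horizontally (frequency
  vector along +x).
* The conjugate half-plane of every oriented mask is zero; self-inverting
  tiling therefore holds in the "conjugate-pair" sense checked by
  :func:`tiling_error`: ``hi^2 + lo^2 + sum_l (B_l(w)^2 + B_l(-w)^2) = 1``
  at every non-DC frequency sample.
* Parseval under this convention:
  ``2 * sum_l ||R_l||^2 + ||hi||^2 + ||lo||^2 = ||frame||^2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "FilterBank",
    "Subband",
    "build_filter_bank",
    "decompose",
    "max_feasible_scales",
    "tiling_error",
    "conjugate_mirror",
]


class FilterBankConfigError(ValueError):
    """Requested bank geometry does not fit the pixel grid."""


@dataclass(frozen=True)
class LevelMeta:
    """Bookkeeping for one band-pass level."""

    scale: int              # 0 = finest (highest radial frequency)
    orientation: int        # index k
    angle: float            # radians, in [0, pi)
    radial_band: tuple[float, float]  # (low, high) edge of the raised-cosine support


@dataclass(frozen=True)
class Subband:
    """One complex band-pass image ``R_l = A_l * exp(j*phi_l)``."""

    level: int
    data: np.ndarray  # complex 2-D array

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.data)

    @property
    def phase(self) -> np.ndarray:
        """Wrapped local phase in (-pi, pi]."""
        phi = np.angle(self.data)
        # numpy returns [-pi, pi]; fold -pi onto +pi for the half-open interval
        return np.where(phi == -np.pi, np.pi, phi)


@dataclass
class FilterBank:
    """Frequency-domain masks of a non-decimated complex steerable pyramid."""

    image_shape: tuple[int, int]
    n_scales: int
    n_orientations: int
    masks: list[np.ndarray]
    hipass_mask: np.ndarray
    lopass_mask: np.ndarray
    level_meta: list[LevelMeta]
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def n_levels(self) -> int:
        return len(self.masks)


def max_feasible_scales(image_shape: Sequence[int]) -> int:
    """Largest scale count whose finest low edge is still resolvable.

    Scale ``s`` occupies the octave ``[pi * 2^-(s+1), pi * 2^-s]``; the lowest
    transition must stay above the fundamental frequency ``2*pi/min(shape)``.
    """
    min_dim = min(int(image_shape[0]), int(image_shape[1]))
    return max(int(np.floor(np.log2(min_dim))) - 2, 0)


def _radial_hi(r: np.ndarray, cutoff: float) -> np.ndarray:
    """Raised-cosine high-pass edge: 0 below cutoff/2, 1 above cutoff."""
    with np.errstate(divide="ignore"):
        t = np.clip(np.log2(np.maximum(r, 1e-300) / cutoff), -1.0, 0.0)
    return np.cos(np.pi / 2.0 * (-t))


def _angular_windows(theta: np.ndarray, n_orientations: int) -> list[np.ndarray]:
    """Half-plane ``cos^(K-1)`` lobes, numerically normalised so that
    ``sum_k g_k(theta)^2 + g_k(theta+pi)^2 = 1``."""
    K = n_orientations
    lobes = []
    for k in range(K):
        dt = np.mod(theta - np.pi * k / K + np.pi, 2 * np.pi) - np.pi
        c = np.cos(dt)
        if K == 1:
            # indicator half-plane; split the boundary ray evenly
            g = np.sqrt((c > 1e-12) * 1.0 + 0.5 * (np.abs(c) <= 1e-12))
        else:
            g = np.where(np.abs(dt) < np.pi / 2, np.maximum(c, 0.0) ** (K - 1), 0.0)
        lobes.append(g)
    # conjugate-pair sum is constant in theta for cos^(K-1) lobes; normalise
    # numerically to kill the combinatorial constant and roundoff
    total = np.zeros_like(theta)
    for g in lobes:
        total += g**2
    # add the conjugate lobes: g_k(theta + pi) is g evaluated at mirrored dt
    for k in range(K):
        dt = np.mod(theta - np.pi * k / K, 2 * np.pi) - np.pi  # theta+pi shift
        c = np.cos(dt)
        if K == 1:
            g = np.sqrt((c > 1e-12) * 1.0 + 0.5 * (np.abs(c) <= 1e-12))
        else:
            g = np.where(np.abs(dt) < np.pi / 2, np.maximum(c, 0.0) ** (K - 1), 0.0)
        total += g**2
    norm = np.sqrt(np.maximum(total, 1e-300))
    return [g / norm for g in lobes]


def build_filter_bank(
    image_shape: Sequence[int], n_scales: int, n_orientations: int
) -> FilterBank:
    """Construct the CSP masks for frames of ``image_shape``.

    Parameters
    ----------
    image_shape
        (rows, cols) of the frames to be decomposed; both >= 16.
    n_scales
        Number of full-octave radial bands (finest first).
    n_orientations
        Number of angular lobes spanning [0, pi).

    Raises
    ------
    FilterBankConfigError
        If the grid is too small for the requested scale count.
    """
    rows, cols = int(image_shape[0]), int(image_shape[1])
    if rows < 16 or cols < 16:
        raise FilterBankConfigError(
            f"image_shape {rows}x{cols} too small; both dimensions must be >= 16"
        )
    if n_scales < 1 or n_orientations < 1:
        raise FilterBankConfigError("n_scales and n_orientations must be >= 1")
    feasible = max_feasible_scales((rows, cols))
    if n_scales > feasible:
        raise FilterBankConfigError(
            f"n_scales={n_scales} infeasible for {rows}x{cols} frames; "
            f"maximum feasible scale count is {feasible}"
        )

    wy = 2 * np.pi * np.fft.fftfreq(rows)[:, None]
    wx = 2 * np.pi * np.fft.fftfreq(cols)[None, :]
    r = np.hypot(wx, wy)
    theta = np.arctan2(wy, wx)

    ang = _angular_windows(theta, n_orientations)

    cutoffs = [np.pi * 2.0 ** (-s) for s in range(n_scales + 1)]
    hipass = _radial_hi(r, cutoffs[0])
    hipass[0, 0] = 0.0

    masks: list[np.ndarray] = []
    meta: list[LevelMeta] = []
    for s in range(n_scales):
        hi_inner = _radial_hi(r, cutoffs[s + 1])
        lo_outer = np.sqrt(np.maximum(0.0, 1.0 - _radial_hi(r, cutoffs[s]) ** 2))
        radial = hi_inner * lo_outer
        radial[0, 0] = 0.0
        for k in range(n_orientations):
            masks.append(radial * ang[k])
            meta.append(
                LevelMeta(
                    scale=s,
                    orientation=k,
                    angle=np.pi * k / n_orientations,
                    radial_band=(cutoffs[s + 1] / 2.0, cutoffs[s]),
                )
            )

    lopass = np.sqrt(np.maximum(0.0, 1.0 - _radial_hi(r, cutoffs[n_scales]) ** 2))
    lopass[0, 0] = 1.0  # DC belongs entirely to the low-pass residual

    return FilterBank(
        image_shape=(rows, cols),
        n_scales=n_scales,
        n_orientations=n_orientations,
        masks=masks,
        hipass_mask=hipass,
        lopass_mask=lopass,
        level_meta=meta,
    )


def conjugate_mirror(mask: np.ndarray) -> np.ndarray:
    """Return ``M(-w)`` on the fft grid, i.e. the conjugate-frequency mirror."""
    return np.roll(mask[::-1, ::-1], (1, 1), axis=(0, 1))


def tiling_error(bank: FilterBank) -> float:
    """Max deviation of the squared-mask tiling from 1 over non-DC samples.

    The oriented masks live on half-planes, so each band contributes both its
    own sample and its conjugate mirror.
    """
    total = bank.hipass_mask**2 + bank.lopass_mask**2
    for m in bank.masks:
        total = total + m**2 + conjugate_mirror(m) ** 2
    total[0, 0] = 1.0  # DC excluded from the check
    return float(np.max(np.abs(total - 1.0)))


def decompose(
    frame: np.ndarray, bank: FilterBank, include_residuals: bool = False
):
    """Band-pass decompose one grayscale frame.

    Returns a list of :class:`Subband` (one per band-pass level).  With
    ``include_residuals=True`` returns ``(subbands, hipass_img, lopass_img)``
    where the residual images are real (their masks are conjugate-symmetric).
    """
    frame = np.asarray(frame)
    if frame.ndim != 2 or frame.shape != bank.image_shape:
        raise ValueError(
            f"frame shape {frame.shape} does not match bank shape {bank.image_shape}"
        )
    if np.iscomplexobj(frame):
        raise ValueError("frame must be real-valued grayscale")
    spectrum = np.fft.fft2(frame.astype(np.float64))
    subbands = [
        Subband(level=l, data=np.fft.ifft2(spectrum * m))
        for l, m in enumerate(bank.masks)
    ]
    if not include_residuals:
        return subbands
    hi = np.fft.ifft2(spectrum * bank.hipass_mask).real
    lo = np.fft.ifft2(spectrum * bank.lopass_mask).real
    return subbands, hi, lo
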