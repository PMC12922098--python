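"""Measure a known sub-pixel shift with the phase-based motion microscope.

Builds a seeded random texture, translates it by exact spectral shifts of
0.3 px and 0.01 px, and reads the displacement back through the complex
steerable pyramid + weighted least-squares estimator. The printed relative
errors show the estimator resolving motion far below one pixel.
"""

import numpy as np
from scipy.ndimage import gaussian_filter

from okntrack import build_filter_bank, extract_point_trace

rng = np.random.default_rng(7)
texture = gaussian_filter(rng.normal(size=(192, 192)), 1.5)
texture = (texture - texture.min()) * 255.0 / np.ptp(texture)


def fft_shift(img, dx):
    wx = 2 * np.pi * np.fft.fftfreq(img.shape[1])[None, :]
    return np.fft.ifft2(np.fft.fft2(img) * np.exp(-1j * wx * dx)).real


bank = build_filter_bank((192, 192), n_scales=5, n_orientations=4)
print(f"filter bank: {bank.n_levels} oriented levels + 2 residuals")

for delta in (0.3, 0.01):
    video = np.stack([texture] + [fft_shift(texture, delta)] * 4)
    trace = extract_point_trace(video, bank, point=(96, 96))
    est = float(np.median(trace.dx[1:]))
    print(
        f"true shift {delta:>5.2f} px -> estimated {est:8.5f} px "
        f"(relative error {abs(est - delta) / delta:.2%}, "
        f"vertical leakage {np.max(np.abs(trace.dy[1:])):.4f} px)"
    )
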