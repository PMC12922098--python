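"""Video and configuration file I/O for the command-line tools.

Videos are exchanged as multi-page TIFF stacks (``.tif``/``.tiff``) or raw
NumPy arrays (``.npy``), both holding a (T, H, W) grayscale stack.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile
import yaml

__all__ = ["load_video", "save_video", "load_yaml"]


def load_video(path) -> np.ndarray:
    path = Path(path)
    if path.suffix == ".npy":
        video = np.load(path)
    elif path.suffix in (".tif", ".tiff"):
        video = tifffile.imread(path)
    else:
        raise ValueError(f"unsupported video format {path.suffix!r} (use .npy/.tif)")
    video = np.asarray(video)
    if video.ndim == 2:
        video = video[None]
    if video.ndim != 3:
        raise ValueError(f"expected a (T, H, W) grayscale stack, got {video.shape}")
    return video


def save_video(path, video: np.ndarray) -> None:
    path = Path(path)
    video = np.asarray(video)
    if path.suffix == ".npy":
        np.save(path, video)
    elif path.suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, video.astype(np.float32))
    else:
        raise ValueError(f"unsupported video format {path.suffix!r} (use .npy/.tif)")


def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}
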