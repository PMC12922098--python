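"""Displacement time series with missing-sample support."""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["DisplacementTrace"]


@dataclass
class DisplacementTrace:
    """Horizontal/vertical displacement over time, relative to the first sample.

    ``valid`` marks samples where an estimate exists; invalid samples carry
    NaN displacement.  ``units`` is ``"px"`` for video-derived traces and
    ``"deg"`` for eye-tracker gaze.  ``source`` tags the producing method
    (``gaze`` | ``centroid`` | ``mmic`` | ``synthetic``).
    """

    t: np.ndarray
    dx: np.ndarray
    dy: np.ndarray
    valid: np.ndarray
    units: str = "px"
    source: str = "unknown"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.dx = np.asarray(self.dx, dtype=float)
        self.dy = np.asarray(self.dy, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.t)
        if not (len(self.dx) == len(self.dy) == len(self.valid) == n):
            raise ValueError("t, dx, dy, valid must have equal length")
        if n > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("time axis must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def sampling_rate(self) -> float:
        if len(self.t) < 2:
            raise ValueError("need at least two samples to infer a rate")
        return 1.0 / float(np.median(np.diff(self.t)))

    @property
    def loss_fraction(self) -> float:
        return 1.0 - float(np.count_nonzero(self.valid)) / len(self.valid)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_s": self.t,
                "dx": self.dx,
                "dy": self.dy,
                "valid": self.valid.astype(int),
                "units": self.units,
                "source": self.source,
            }
        )

    def to_csv(self, path_or_buf) -> None:
        """Write the trace as CSV; a leading comment line records metadata."""
        header = "# " + "; ".join(f"{k}={v}" for k, v in sorted(self.meta.items()))
        df = self.to_frame()
        if hasattr(path_or_buf, "write"):
            path_or_buf.write(header + "\n")
            df.to_csv(path_or_buf, index=False)
        else:
            with open(path_or_buf, "w") as fh:
                fh.write(header + "\n")
                df.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path_or_buf) -> "DisplacementTrace":
        if hasattr(path_or_buf, "read"):
            text = path_or_buf.read()
        else:
            with open(path_or_buf) as fh:
                text = fh.read()
        meta: dict = {}
        lines = text.splitlines()
        body_start = 0
        for i, line in enumerate(lines):
            if line.startswith("#"):
                for item in line.lstrip("# ").split(";"):
                    if "=" in item:
                        k, v = item.split("=", 1)
                        meta[k.strip()] = v.strip()
                body_start = i + 1
            else:
                break
        df = pd.read_csv(io.StringIO("\n".join(lines[body_start:])))
        return cls(
            t=df["t_s"].to_numpy(),
            dx=df["dx"].to_numpy(),
            dy=df["dy"].to_numpy(),
            valid=df["valid"].to_numpy().astype(bool),
            units=str(df["units"].iloc[0]) if len(df) else "px",
            source=str(df["source"].iloc[0]) if len(df) else "unknown",
            meta=meta,
        )
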