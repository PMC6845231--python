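"""In-memory movie container and TIFF I/O."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["Movie"]


@dataclass
class Movie:
    """A single-channel T x H x W image time series with per-frame timestamps."""

    data: np.ndarray        # (T, H, W)
    timestamps: np.ndarray  # (T,) seconds

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("movie data must be T x H x W")
        if len(self.timestamps) != self.data.shape[0]:
            raise ValueError("one timestamp per frame required")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    def save_tiff(self, path) -> None:
        """Write as a multi-page 16-bit TIFF plus a timestamp sidecar JSON.

        Float data are rounded and clipped into the uint16 range.
        """
        path = Path(path)
        arr = self.data
        if arr.dtype != np.uint16:
            arr = np.clip(np.rint(arr), 0, np.iinfo(np.uint16).max).astype(np.uint16)
        tifffile.imwrite(path, arr)
        with open(path.with_suffix(".times.json"), "w") as fh:
            json.dump({"timestamps_s": self.timestamps.tolist()}, fh)

    @classmethod
    def from_tiff(cls, path, frame_rate_hz: float | None = None) -> "Movie":
        """Read a multi-page TIFF; timestamps come from the sidecar JSON if
        present, else from ``frame_rate_hz``."""
        path = Path(path)
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
        sidecar = path.with_suffix(".times.json")
        if sidecar.exists():
            with open(sidecar) as fh:
                ts = np.asarray(json.load(fh)["timestamps_s"], dtype=float)
        elif frame_rate_hz is not None:
            ts = np.arange(data.shape[0]) / frame_rate_hz
        else:
            raise ValueError("no timestamp sidecar found; pass frame_rate_hz")
        return cls(data=data.astype(float), timestamps=ts)
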