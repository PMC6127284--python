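"""Calibrated time-lapse movie container.

A :class:`Movie` is the raw data of the pulse-chase assay: a stack of
single-channel frames (the photoconverted red signal) with the physical
calibration needed to convert pixels and frames into micrometres and
seconds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile


@dataclass
class Movie:
    """Single-channel time-lapse stack with physical calibration.

    Parameters
    ----------
    frames:
        Array of shape ``(T, H, W)``, non-negative intensities.
    pixel_size:
        Lateral pixel size in micrometres.
    frame_interval:
        Nominal spacing between frames in seconds.
    timepoints:
        Acquisition times in seconds, strictly increasing, starting at 0.
        Defaults to a uniform grid ``0, dt, 2 dt, ...``.
    """

    frames: np.ndarray
    pixel_size: float
    frame_interval: float
    timepoints: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) array")
        if np.any(self.frames < 0):
            raise ValueError("intensities must be non-negative")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("pixel_size and frame_interval must be positive")
        if self.timepoints is None:
            self.timepoints = np.arange(self.n_frames) * self.frame_interval
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        if len(self.timepoints) != self.n_frames:
            raise ValueError("timepoints must match frame count")
        if self.timepoints[0] != 0 or np.any(np.diff(self.timepoints) <= 0):
            raise ValueError("timepoints must start at 0 and strictly increase")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """Frame shape ``(H, W)``."""
        return self.frames.shape[1:]

    def scaled(self, gain: float) -> "Movie":
        """Return a copy with all intensities multiplied by ``gain`` > 0."""
        if gain <= 0:
            raise ValueError("gain must be positive")
        return Movie(self.frames * gain, self.pixel_size, self.frame_interval,
                     self.timepoints.copy())

    def save(self, path: str | Path) -> None:
        """Write as multi-page TIFF with a JSON calibration sidecar."""
        path = Path(path)
        tifffile.imwrite(path, self.frames.astype(np.float32),
                         photometric="minisblack")
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps({
            "pixel_size_um": self.pixel_size,
            "frame_interval_s": self.frame_interval,
            "timepoints_s": self.timepoints.tolist(),
        }))

    @classmethod
    def load(cls, path: str | Path) -> "Movie":
        path = Path(path)
        frames = tifffile.imread(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(frames=np.asarray(frames, dtype=float),
                   pixel_size=meta["pixel_size_um"],
                   frame_interval=meta["frame_interval_s"],
                   timepoints=np.asarray(meta["timepoints_s"]))
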