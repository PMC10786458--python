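"""Core data containers shared by all analysis stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile

# Default pixel size in µm/px, back-computed from a 6 px ~ 0.74 µm border
# cutoff; the alternative reading 4 px ~ 0.5 µm gives 0.125 µm/px.
DEFAULT_PIXEL_SIZE_UM = 0.1233
#: acquisition rate of the stimulation protocol, frames per second
DEFAULT_FRAME_RATE_HZ = 4.0
#: baseline / stimulation-onset time, s
DEFAULT_T_ON_S = 20.0
#: stimulation-off time, s
DEFAULT_T_OFF_S = 30.0
#: total protocol duration, s (20 s baseline + 10 s stimulus + 30 s recovery)
DEFAULT_DURATION_S = 60.0


@dataclass
class ImageStack:
    """A timestamped fluorescence image sequence with physical pixel size.

    Parameters
    ----------
    frames
        Intensity array of shape ``(t, y, x)``, non-negative, finite.
    timestamps
        Acquisition times in seconds, strictly increasing.
    pixel_size
        Lateral pixel size in µm/pixel.
    channel
        Free-form channel label (e.g. ``"H2b"``, ``"nucleolus-stain"``).
    """

    frames: np.ndarray
    timestamps: np.ndarray
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM
    channel: str = "H2b"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (t, y, x) array")
        if self.frames.shape[0] != self.timestamps.shape[0]:
            raise ValueError("one timestamp per frame required")
        if self.timestamps.size > 1 and np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frame intensities must be finite")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def save_tiff(self, path) -> None:
        """Write as a multi-frame float32 TIFF."""
        tifffile.imwrite(path, self.frames.astype(np.float32),
                         photometric="minisblack")

    @classmethod
    def from_tiff(cls, path, pixel_size: float = DEFAULT_PIXEL_SIZE_UM,
                  frame_interval: float = 1.0 / DEFAULT_FRAME_RATE_HZ,
                  channel: str = "H2b") -> "ImageStack":
        """Read a multi-frame TIFF; timestamps from a uniform frame interval."""
        frames = tifffile.imread(path)
        frames = np.atleast_3d(frames)
        if frames.ndim == 2:
            frames = frames[None]
        t = np.arange(frames.shape[0]) * frame_interval
        return cls(frames=frames.astype(float), timestamps=t,
                   pixel_size=pixel_size, channel=channel)


@dataclass
class TimeSeries:
    """A scalar metric sampled over the stimulation protocol.

    ``stimulus_window`` holds ``(t_on, t_off)`` in seconds; values may be
    image-difference units (a.u.), displacement (µm) or strain (relative).
    """

    t: np.ndarray
    value: np.ndarray
    stimulus_window: tuple[float, float] = (DEFAULT_T_ON_S, DEFAULT_T_OFF_S)
    label: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.t.shape != self.value.shape:
            raise ValueError("t and value must have equal shape")

    @property
    def t_on(self) -> float:
        return self.stimulus_window[0]

    @property
    def t_off(self) -> float:
        return self.stimulus_window[1]
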