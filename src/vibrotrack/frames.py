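"""Time-ordered luminance frame stacks.

The whole pipeline operates on grayscale frame stacks: a ``(T, H, W)``
float array with values in ``[0, 1]`` plus the acquisition frame rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FrameStack"]


@dataclass
class FrameStack:
    """An ordered sequence of grayscale luminance frames.

    Parameters
    ----------
    frames : ndarray, shape (T, H, W)
        Luminance values in ``[0, 1]``.
    fps : float
        Frame rate in Hz.
    """

    frames: np.ndarray
    fps: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be (T, H, W), got shape {self.frames.shape}")
        if self.frames.shape[0] < 2:
            raise ValueError("a frame stack needs at least two frames")
        if not self.fps > 0:
            raise ValueError(f"fps must be positive, got {self.fps}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]  # type: ignore[return-value]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    @property
    def times(self) -> np.ndarray:
        """Sample times of each frame in seconds (frame 0 at t=0)."""
        return np.arange(self.n_frames) / self.fps

    def copy(self) -> "FrameStack":
        return FrameStack(self.frames.copy(), self.fps)
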