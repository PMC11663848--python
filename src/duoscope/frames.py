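"""The in-memory video container used throughout the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np


@dataclass
class FrameStack:
    """A single-channel grayscale video with acquisition metadata.

    ``data`` is a (T, H, W) array in acquisition order.  ``channel`` is
    ``"green"``, ``"red"`` or ``"interleaved"``; ``fps`` is the sensor
    frame rate of this stream (after de-interleaving, half the sensor
    rate).  ``meta`` carries trial-level annotations such as the EWL PWM
    duty cycle or ground-truth fields from the synthetic generators.
    """

    data: np.ndarray
    fps: float = 10.0
    channel: str = "interleaved"
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("FrameStack data must be (T, H, W)")
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    def __len__(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    def time_average(self) -> np.ndarray:
        """Pixel-wise mean over frames (float64)."""
        if len(self) == 0:
            raise ValueError("empty stack has no time average")
        return self.data.mean(axis=0, dtype=np.float64)
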