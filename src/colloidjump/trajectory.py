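"""In-memory containers for 2D particle-tracking trajectories."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Trajectory:
    """Time-ordered 2D positions of one tracked particle.

    ``xy`` has shape (n_frames, 2) in um; ``t`` are the acquisition times
    in seconds at a constant frame interval.
    """

    track_id: int
    t: np.ndarray
    xy: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, float)
        self.xy = np.asarray(self.xy, float)
        if self.xy.ndim != 2 or self.xy.shape[1] != 2:
            raise ValueError("xy must have shape (n_frames, 2)")
        if self.t.shape[0] != self.xy.shape[0]:
            raise ValueError("t and xy must have the same length")

    def __len__(self) -> int:
        return self.t.shape[0]

    @property
    def dt(self) -> float:
        """Frame interval (s); raises if sampling is not uniform."""
        if len(self) < 2:
            raise ValueError("trajectory too short to define a frame interval")
        steps = np.diff(self.t)
        dt = float(steps[0])
        if dt <= 0 or not np.allclose(steps, dt, rtol=1e-6, atol=1e-9):
            raise ValueError(f"non-uniform sampling in track {self.track_id}")
        return dt


@dataclass
class TrueJump:
    """Ground-truth jump event written by the synthetic generator.

    Displacement frames [frame_start, frame_end) belong to the jump;
    (dx, dy) is the realised displacement in channel coordinates (after
    wall stopping, if any).  ``censored`` marks jumps cut short by the end
    of the recording.
    """

    frame_start: int
    frame_end: int
    x0: float
    y0: float
    dx: float
    dy: float
    censored: bool = False

    @property
    def magnitude(self) -> float:
        return float(np.hypot(self.dx, self.dy))


@dataclass
class LabelledTrajectory(Trajectory):
    """Trajectory plus per-frame jump labels and true jump events.

    ``in_jump[i]`` is True when the displacement from frame i to i+1 is
    part of an active jump (the last entry is always False).
    """

    in_jump: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))
    events: list[TrueJump] = field(default_factory=list)

    def __post_init__(self):
        super().__post_init__()
        self.in_jump = np.asarray(self.in_jump, bool)
        if self.in_jump.shape[0] != len(self):
            raise ValueError("in_jump must have one entry per frame")
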