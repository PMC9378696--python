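"""Segmentation of trajectories into diffusive motion and active jumps.

A frame-to-frame displacement is a jump candidate when it is both large
compared to the expected diffusive step (``> k * sqrt(4 D0 dt)``) and
directionally correlated with an adjacent displacement (cosine with the
previous or the next displacement above a threshold — fast entrainment
segments are nearly straight, diffusive steps are not).  Candidate frames
separated by at most ``merge_gap`` frames are merged into one event and
events shorter than ``min_frames`` displacement frames are discarded.

Event coordinates follow the folded channel convention: ``y`` is the
distance from the nearest wall, the projection ``y_J`` is positive away
from that wall, and the jump angle ``theta = atan2(y_J, dx)`` is zero for
wall-parallel motion and negative toward the wall.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .profiles import Geometry
from .trajectory import Trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "DetectionParams",
    "JumpEvent",
    "detect_jumps",
    "frame_labels",
    "waiting_times",
    "default_bin_edges",
    "bin_by_wall_distance",
]


@dataclass(frozen=True)
class DetectionParams:
    k_sigma: float = 3.0  # displacement threshold, multiples of sqrt(4 D0 dt)
    min_cos: float = 0.5  # directional-correlation threshold
    min_frames: int = 2  # minimum event length, displacement frames
    merge_gap: int = 1  # candidates this many frames apart are merged

    def __post_init__(self):
        if self.k_sigma <= 0 or not (-1.0 <= self.min_cos <= 1.0):
            raise ValueError("invalid detection thresholds")
        if self.min_frames < 1 or self.merge_gap < 0:
            raise ValueError("invalid event-length parameters")


@dataclass
class JumpEvent:
    """One detected active displacement."""

    track_id: int
    frame_start: int
    frame_end: int  # displacement frames [frame_start, frame_end) are in-jump
    x0: float  # start position, channel coordinates (um)
    y0: float  # start distance from the nearest wall (um)
    dx: float  # wall-parallel displacement (um)
    dy: float  # wall-normal displacement, channel coordinates (um)
    y_J: float  # signed wall-normal projection, + away from the wall (um)
    theta: float  # jump angle, 0 = wall-parallel, < 0 toward the wall
    magnitude: float  # |(dx, dy)| (um)
    duration: float  # s


def detect_jumps(
    traj: Trajectory,
    geometry: Geometry,
    params: DetectionParams,
    D0: float,
    dt: float | None = None,
) -> list[JumpEvent]:
    """Detect active jumps along one trajectory.

    Returns non-overlapping events sorted by frame.  Trajectories with
    fewer than 3 frames yield no events; non-uniform sampling raises.
    """
    n = len(traj)
    if n < 3:
        return []
    if dt is None:
        dt = traj.dt  # validates uniform sampling
    d = np.diff(traj.xy, axis=0)
    mag = np.hypot(d[:, 0], d[:, 1])
    thr = params.k_sigma * np.sqrt(4.0 * D0 * dt)
    big = mag > thr
    num = (d[:-1] * d[1:]).sum(axis=1)
    den = mag[:-1] * mag[1:]
    cos = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    aligned = cos > params.min_cos
    corr = np.zeros(d.shape[0], dtype=bool)
    corr[:-1] |= aligned  # correlated with the next displacement
    corr[1:] |= aligned  # correlated with the previous displacement
    cand = big & corr
    idx = np.nonzero(cand)[0]
    if idx.size == 0:
        return []

    events = []
    breaks = np.nonzero(np.diff(idx) > params.merge_gap + 1)[0]
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [idx.size - 1]])
    W = geometry.half_width
    for s, e in zip(starts, ends):
        i0, i1 = int(idx[s]), int(idx[e])
        if i1 - i0 + 1 < params.min_frames:
            continue
        X0, Y0 = traj.xy[i0]
        dxv = traj.xy[i1 + 1, 0] - X0
        dyv = traj.xy[i1 + 1, 1] - Y0
        y_wall = float(min(Y0, 2 * W - Y0))
        y_J = float(dyv if Y0 <= W else -dyv)
        events.append(
            JumpEvent(
                track_id=traj.track_id,
                frame_start=i0,
                frame_end=i1 + 1,
                x0=float(X0),
                y0=y_wall,
                dx=float(dxv),
                dy=float(dyv),
                y_J=y_J,
                theta=float(np.arctan2(y_J, dxv)),
                magnitude=float(np.hypot(dxv, dyv)),
                duration=float((i1 + 1 - i0) * dt),
            )
        )
    return events


def frame_labels(n_frames: int, events) -> np.ndarray:
    """Per-frame jump/diffusive labels implied by a list of events."""
    lab = np.zeros(n_frames, dtype=bool)
    for ev in events:
        lab[ev.frame_start : ev.frame_end] = True
    return lab


def waiting_times(events, traj: Trajectory, geometry: Geometry):
    """Waits between consecutive jumps of one trajectory.

    Returns ``(y, wait)`` arrays with one sample per consecutive event
    pair: the wall distance at the end of the previous jump (where the
    wait starts) and the elapsed time to the start of the next jump.
    Censored waits at the trajectory ends are excluded by construction.
    """
    if len(events) < 2:
        return np.empty(0), np.empty(0)
    events = sorted(events, key=lambda e: e.frame_start)
    dt = traj.dt
    W = geometry.half_width
    ys, waits = [], []
    for prev, nxt in zip(events[:-1], events[1:]):
        gap = nxt.frame_start - prev.frame_end
        if gap <= 0:
            continue
        Y = traj.xy[prev.frame_end, 1]
        ys.append(min(Y, 2 * W - Y))
        waits.append(gap * dt)
    return np.asarray(ys), np.asarray(waits)


def default_bin_edges(geometry: Geometry, width: float = 10.0 / 3.0) -> np.ndarray:
    """Wall-distance bin edges centred on y_col, y_col + width, ... up to W.

    With the default 10/3 um width and y_col = a = 5 um this reproduces
    the standard binning (centres 5.0, 8.3, 11.7, ... um).
    """
    lo = geometry.y_col - width / 2.0
    n = int(round((geometry.half_width - lo) / width))
    return lo + width * np.arange(n + 1)


def bin_by_wall_distance(y, edges):
    """Assign wall-distance samples to bins; both walls are folded together.

    Samples outside the edge range are assigned to the nearest edge bin;
    their count is returned and logged.  Returns ``(bin_index, n_outside)``
    with ``bin_index`` in ``[0, len(edges) - 2]``.
    """
    y = np.asarray(y, float)
    edges = np.asarray(edges, float)
    idx = np.digitize(y, edges) - 1
    outside = (idx < 0) | (idx > edges.size - 2)
    n_out = int(outside.sum())
    if n_out:
        logger.warning("%d samples outside the bin range; assigned to edge bins", n_out)
    idx = np.clip(idx, 0, edges.size - 2)
    return idx, n_out
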