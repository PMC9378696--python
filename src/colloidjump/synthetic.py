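"""Synthetic 2D trajectories and de-mixing series with ground truth.

The generator emulates what 10 fps particle tracking of weakly Brownian
colloids in a channel filled with swimming algae produces: slow thermal
diffusion (D0 ~ 0.044 um^2/s) interrupted by Poisson-distributed fast
jumps whose rate and wall-normal size distribution follow a configured
:class:`~colloidjump.profiles.ActivityField`.  Every jump is recorded with
its true frames and displacement, so detection and fitting can be scored
against ground truth without any experimental data.

Model choices (see docs/methods.md):

* The wall-normal jump component y_J is drawn exactly from the kernel
  q_y(y_J) at the jump's starting wall distance; the wall-parallel
  component is an independent two-sided exponential with the bulk jump
  length as scale.  Near the wall L± are small while the parallel scale is
  not, so jumps become preferentially wall-parallel, as observed.
* Jumps are rendered as straight segments spanning
  max(min_jump_frames, ceil(length / (v_jump * dt))) frames; the 2-frame
  floor models the finite duration of an algal encounter and makes events
  resolvable by correlation-based detection.
* A jump whose straight path would cross a wall stops at the wall offset
  (one colloid radius from the boundary); diffusive steps reflect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .profiles import ActivityField, Geometry, sample_jump
from .trajectory import LabelledTrajectory, TrueJump

__all__ = ["SynthConfig", "generate_channel_trajectories", "DemixSeries", "generate_demix_series"]


@dataclass
class SynthConfig:
    geometry: Geometry
    field: ActivityField
    D0: float = 0.0439  # um^2/s
    dt: float = 0.1  # s
    v_jump: float = 30.0  # um/s, in-jump speed
    min_jump_frames: int = 2
    L_parallel: float | None = None  # wall-parallel jump scale; default bulk L
    localization_noise: float = 0.0  # um, sd added to recorded positions
    n_particles: int = 50
    n_frames: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.min_jump_frames < 1:
            raise ValueError("min_jump_frames must be >= 1")


def generate_channel_trajectories(config: SynthConfig) -> list[LabelledTrajectory]:
    """Generate labelled 2D trajectories in the channel.

    Returns one :class:`LabelledTrajectory` per particle; output is a
    deterministic function of ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    geo, fld = config.geometry, config.field
    n, m, dt = config.n_particles, config.n_frames, config.dt
    ylo, yhi = geo.y_bounds()
    W = geo.half_width

    Lpar = config.L_parallel if config.L_parallel is not None else fld.bulk_L()
    sigma = math.sqrt(2.0 * config.D0 * dt)
    step_len = config.v_jump * dt

    x = np.zeros(n)
    y = rng.uniform(ylo, yhi, n)
    pos = np.empty((m, n, 2))
    pos[0, :, 0] = x
    pos[0, :, 1] = y
    in_jump = np.zeros((m, n), dtype=bool)
    remaining = np.zeros(n, dtype=int)
    vel = np.zeros((n, 2))
    open_events: list[dict | None] = [None] * n
    events: list[list[TrueJump]] = [[] for _ in range(n)]

    for t in range(m - 1):
        free = remaining == 0
        yd = np.minimum(y, 2 * W - y)
        lam = np.asarray(fld.lambda_at(yd), float)
        start = free & (rng.random(n) < lam * dt)
        if start.any():
            idx = np.nonzero(start)[0]
            yJ = np.atleast_1d(sample_jump(fld, yd[idx], rng, size=idx.size))
            dy = np.where(y[idx] <= W, yJ, -yJ)
            mag_par = rng.exponential(Lpar, idx.size)
            dx = np.where(rng.random(idx.size) < 0.5, mag_par, -mag_par)
            # stopping rule: truncate the straight segment at the wall offset
            target = y[idx] + dy
            frac = np.ones(idx.size)
            over = target > yhi
            under = target < ylo
            frac[over] = (yhi - y[idx][over]) / dy[over]
            frac[under] = (ylo - y[idx][under]) / dy[under]
            dy = dy * frac
            dx = dx * frac
            mag = np.hypot(dx, dy)
            nfr = np.maximum(config.min_jump_frames, np.ceil(mag / step_len)).astype(int)
            remaining[idx] = nfr
            vel[idx, 0] = dx / nfr
            vel[idx, 1] = dy / nfr
            for k, i in enumerate(idx):
                open_events[i] = {
                    "frame_start": t,
                    "x0": x[i],
                    "y0": y[i],
                    "dx": dx[k],
                    "dy": dy[k],
                }
        active = remaining > 0
        in_jump[t, active] = True
        x = x + np.where(active, vel[:, 0], 0.0)
        y_new = y + np.where(active, vel[:, 1], 0.0)
        n_free = int((~active).sum())
        if n_free and config.D0 > 0:
            steps = rng.normal(0.0, sigma, (n_free, 2))
            fidx = np.nonzero(~active)[0]
            x[fidx] += steps[:, 0]
            y_new[fidx] += steps[:, 1]
            # reflective walls for diffusive moves
            y_new[fidx] = _reflect(y_new[fidx], ylo, yhi)
        y = y_new
        pos[t + 1, :, 0] = x
        pos[t + 1, :, 1] = y
        remaining[active] -= 1
        done = active & (remaining == 0)
        for i in np.nonzero(done)[0]:
            ev = open_events[i]
            events[i].append(
                TrueJump(
                    frame_start=ev["frame_start"],
                    frame_end=t + 1,
                    x0=ev["x0"],
                    y0=ev["y0"],
                    dx=ev["dx"],
                    dy=ev["dy"],
                )
            )
            open_events[i] = None

    # jumps still running at the end of the recording are censored
    for i in np.nonzero(remaining > 0)[0]:
        ev = open_events[i]
        elapsed = (m - 1) - ev["frame_start"]
        total = elapsed + remaining[i]
        events[i].append(
            TrueJump(
                frame_start=ev["frame_start"],
                frame_end=m - 1,
                x0=ev["x0"],
                y0=ev["y0"],
                dx=ev["dx"] * elapsed / total,
                dy=ev["dy"] * elapsed / total,
                censored=True,
            )
        )

    if config.localization_noise > 0:
        pos = pos + rng.normal(0.0, config.localization_noise, pos.shape)

    times = np.arange(m) * dt
    return [
        LabelledTrajectory(
            track_id=i,
            t=times,
            xy=pos[:, i],
            in_jump=in_jump[:, i],
            events=events[i],
        )
        for i in range(n)
    ]


def _reflect(y, lo, hi):
    span = hi - lo
    y = np.mod(y - lo, 2 * span)
    y = np.where(y > span, 2 * span - y, y)
    return y + lo


@dataclass
class DemixSeries:
    """Occupancy time series of the two-compartment de-mixing experiment."""

    t: np.ndarray  # s
    N_c: np.ndarray  # chamber counts
    N_s: np.ndarray  # side-channel counts
    N_t: float
    area_c: float | None = None  # um^2
    area_s: float | None = None

    def __post_init__(self):
        self.t = np.asarray(self.t, float)
        self.N_c = np.asarray(self.N_c, float)
        self.N_s = np.asarray(self.N_s, float)

    @property
    def rho_c(self):
        return self.N_c / self.area_c

    @property
    def rho_s(self):
        return self.N_s / self.area_s


def generate_demix_series(
    k_in: float,
    k_out: float,
    N_total: int,
    t_grid,
    seed: int | None = None,
    noise: str = "none",
) -> DemixSeries:
    """Two-compartment occupancy series at transition rates k_in, k_out (1/s).

    ``noise="none"`` returns the exact first-order-kinetics solution
    starting from all particles in the chamber; ``noise="binomial"``
    simulates each particle as an independent two-state Markov chain
    sampled exactly on ``t_grid``.
    """
    if k_in < 0 or k_out < 0:
        raise ValueError("rates must be >= 0")
    if N_total <= 0:
        raise ValueError("N_total must be > 0")
    t = np.asarray(t_grid, float)
    k = k_in + k_out
    if noise == "none":
        from .demixing import kinetics_solution

        N_c, N_s = kinetics_solution(k_in, k_out, N_total, 0.0, t)
        return DemixSeries(t=t, N_c=N_c, N_s=N_s, N_t=float(N_total))
    if noise != "binomial":
        raise ValueError("noise must be 'none' or 'binomial'")
    rng = np.random.default_rng(seed)
    in_side = np.zeros(N_total, dtype=bool)
    N_s = np.empty(t.shape[0])
    N_s[0] = 0.0
    for j in range(1, t.shape[0]):
        delta = t[j] - t[j - 1]
        if k > 0:
            decay = math.exp(-k * delta)
            p_cs = k_in / k * (1.0 - decay)  # chamber -> side over delta
            p_sc = k_out / k * (1.0 - decay)
        else:
            p_cs = p_sc = 0.0
        u = rng.random(N_total)
        switch = np.where(in_side, u < p_sc, u < p_cs)
        in_side = in_side ^ switch
        N_s[j] = in_side.sum()
    N_c = N_total - N_s
    return DemixSeries(t=t, N_c=N_c, N_s=N_s, N_t=float(N_total))
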