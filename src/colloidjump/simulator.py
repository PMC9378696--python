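"""1D jump-diffusion Monte-Carlo of colloid positions across the channel.

Each time step an acceptance-rejection draw decides between a jump and a
Brownian step: a uniform number in [0, 1] triggers a jump when it falls in
the centred interval [(1 - lambda(y) dt)/2, (1 + lambda(y) dt)/2]
(probability lambda(y) dt), in which case the displacement is drawn from
the kernel q_y by inverse-transform sampling; otherwise the particle takes
a Gaussian step of variance 2 D0 dt.  Jumps that would cross a wall stop
at one colloid radius from it; diffusive crossings reflect.  Jumps are
rendered instantaneously, which is justified because the typical jump
duration is much shorter than the mean waiting time between jumps.

The module also provides the three ablations used to probe which features
of the activity field matter: a constant encounter rate, no thermal
diffusion, and a homogeneous isotropic jump kernel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .profiles import ActivityField, Geometry, sample_jump

__all__ = [
    "SimConfig",
    "SimResult",
    "apply_ablation",
    "simulate",
    "steady_state_histogram",
    "peak_location",
    "tv_distance",
]

ABLATIONS = ("none", "const-rate", "no-diffusion", "homog-kernel")


class _ConstantRateField(ActivityField):
    """Wrapper fixing lambda(y) to the bulk value everywhere."""

    def __init__(self, base: ActivityField):
        self.base = base
        self.geometry = base.geometry
        self._lam = base.bulk_lambda()

    def lambda_at(self, y):
        return np.full_like(np.asarray(y, float), self._lam)

    def L_plus_at(self, y):
        return self.base.L_plus_at(y)

    def L_minus_at(self, y):
        return self.base.L_minus_at(y)

    def bulk_L(self):
        return self.base.bulk_L()

    def bulk_lambda(self):
        return self._lam


class _HomogeneousKernelField(ActivityField):
    """Wrapper fixing the jump kernel to its isotropic bulk form."""

    def __init__(self, base: ActivityField):
        self.base = base
        self.geometry = base.geometry
        self._L = base.bulk_L()

    def lambda_at(self, y):
        return self.base.lambda_at(y)

    def L_plus_at(self, y):
        return np.full_like(np.asarray(y, float), self._L)

    def L_minus_at(self, y):
        return np.full_like(np.asarray(y, float), self._L)

    def bulk_L(self):
        return self._L

    def bulk_lambda(self):
        return self.base.bulk_lambda()


@dataclass
class SimConfig:
    field: ActivityField
    geometry: Geometry
    D0: float = 0.0439
    dt: float = 0.1
    n_traj: int = 100
    n_steps: int = 10_000
    burn_in: int | None = None  # steps discarded; default n_steps // 10
    seed: int | None = None
    ablation: str = "none"
    record_bins: np.ndarray | None = None  # wall-distance edges for rate audit
    store_positions: bool = True  # False: keep only occupancy counts (big runs)

    def __post_init__(self):
        if self.ablation not in ABLATIONS:
            raise ValueError(f"ablation must be one of {ABLATIONS}")
        if self.burn_in is None:
            self.burn_in = self.n_steps // 10
        if self.n_steps <= self.burn_in:
            raise ValueError("n_steps must exceed burn_in")


@dataclass
class SimResult:
    positions: np.ndarray  # (n_traj, n_steps + 1), or (n_traj,) final if not stored
    config: SimConfig
    jump_counts: np.ndarray | None = None  # per record_bin: jumps initiated
    occupancy_steps: np.ndarray | None = None  # per record_bin: steps spent

    def occupancy_histogram(self):
        """Folded post-burn-in density from the occupancy counters.

        Equivalent to :func:`steady_state_histogram` on the stored
        positions but available for memory-light runs
        (``store_positions=False`` with ``record_bins`` set).
        """
        if self.occupancy_steps is None:
            raise ValueError("run was configured without record_bins")
        edges = np.asarray(self.config.record_bins, float)
        widths = np.diff(edges)
        total = self.occupancy_steps.sum()
        centres = 0.5 * (edges[:-1] + edges[1:])
        return centres, self.occupancy_steps / (total * widths)


def apply_ablation(field: ActivityField, which: str) -> ActivityField:
    if which in ("none", "no-diffusion"):
        return field
    if which == "const-rate":
        return _ConstantRateField(field)
    if which == "homog-kernel":
        return _HomogeneousKernelField(field)
    raise ValueError(f"unknown ablation {which!r}")


def simulate(config: SimConfig) -> SimResult:
    """Run the jump-diffusion scheme; returns all positions (um)."""
    fld = apply_ablation(config.field, config.ablation)
    D0 = 0.0 if config.ablation == "no-diffusion" else config.D0
    geo = config.geometry
    dt = config.dt
    ylo, yhi = geo.y_bounds()
    W = geo.half_width
    rng = np.random.default_rng(config.seed)

    lam_max = float(np.max(fld.lambda_at(np.linspace(ylo, W, 256))))
    if lam_max * dt > 1.0:
        raise ValueError("lambda * dt exceeds 1; the acceptance-rejection scheme breaks down")
    if lam_max * dt > 0.1:
        warnings.warn("lambda * dt > 0.1; jump probabilities per step are no longer small")

    n = config.n_traj
    y = rng.uniform(ylo, yhi, n)
    if config.store_positions:
        pos = np.empty((n, config.n_steps + 1))
        pos[:, 0] = y
    else:
        pos = None
        if config.record_bins is None:
            raise ValueError("store_positions=False requires record_bins")
    sigma = np.sqrt(2.0 * D0 * dt)

    edges = config.record_bins
    if edges is not None:
        edges = np.asarray(edges, float)
        jump_counts = np.zeros(edges.size - 1)
        occupancy = np.zeros(edges.size - 1)
    else:
        jump_counts = occupancy = None

    for t in range(config.n_steps):
        yd = np.minimum(y, 2 * W - y)
        lam = np.asarray(fld.lambda_at(yd), float)
        u = rng.random(n)
        p = lam * dt
        jump = (u >= (1.0 - p) / 2.0) & (u <= (1.0 + p) / 2.0)
        if edges is not None and t >= config.burn_in:
            idx = np.clip(np.digitize(yd, edges) - 1, 0, edges.size - 2)
            np.add.at(occupancy, idx, 1)
            np.add.at(jump_counts, idx[jump], 1)
        y_new = y.copy()
        if jump.any():
            j = np.nonzero(jump)[0]
            yJ = np.atleast_1d(sample_jump(fld, yd[j], rng, size=j.size))
            dy = np.where(y[j] <= W, yJ, -yJ)
            y_new[j] = np.clip(y[j] + dy, ylo, yhi)  # stopping rule
        free = ~jump
        if free.any() and D0 > 0:
            step = rng.normal(0.0, sigma, int(free.sum()))
            yf = y[free] + step
            span = yhi - ylo
            yf = np.mod(yf - ylo, 2 * span)
            yf = np.where(yf > span, 2 * span - yf, yf) + ylo
            y_new[free] = yf
        y = y_new
        if pos is not None:
            pos[:, t + 1] = y

    return SimResult(
        positions=pos if pos is not None else y,
        config=config,
        jump_counts=jump_counts,
        occupancy_steps=occupancy,
    )


def steady_state_histogram(
    positions: np.ndarray,
    geometry: Geometry,
    burn_in: int,
    bin_width: float = 1.0,
):
    """Symmetrized post-burn-in density over wall distance.

    Positions are folded onto [y_col, W]; the returned density integrates
    to 1 over that range.  Returns ``(bin_centres, density)``.
    """
    samples = np.asarray(positions)[:, burn_in:]
    folded = geometry.wall_distance(samples.ravel())
    lo, hi = geometry.y_col, geometry.half_width
    n_bins = int(round((hi - lo) / bin_width))
    edges = np.linspace(lo, hi, n_bins + 1)
    density, edges = np.histogram(folded, bins=edges, density=True)
    centres = 0.5 * (edges[:-1] + edges[1:])
    return centres, density


def peak_location(centres, density) -> float:
    """Location (bin centre) of the density maximum."""
    return float(np.asarray(centres)[int(np.argmax(density))])


def tv_distance(density_p, density_q, bin_width: float) -> float:
    """Total-variation distance between two binned densities on one grid."""
    p = np.asarray(density_p, float) * bin_width
    q = np.asarray(density_q, float) * bin_width
    return float(0.5 * np.abs(p - q).sum())
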