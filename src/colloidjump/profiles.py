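"""Space-dependent jump statistics of colloids in a confined active bath.

Swimming microalgae accumulate and reorient near channel walls, which turns
the active kicks they impart on suspended passive colloids into a
position-dependent Poisson process: jumps are initiated at a rate
``lambda(y)`` that depends on the distance ``y`` to the nearest wall, and
the wall-normal projection ``y_J`` of a jump follows a two-sided
exponential kernel

    q_y(y_J) = exp(-|y_J| / L±(y)) / (L+(y) + L-(y)),

where ``L+`` is the characteristic length of jumps directed away from the
wall (``y_J > 0``) and ``L-`` toward it.  All three fields relax
exponentially from a wall value to a bulk value over a few tens of microns:

    L±(y)    = (L_wall - L_bulk) exp(-(y - y_col)/l±) + L_bulk
    lambda(y) = (lambda_wall - lambda_bulk) exp(-(y - y_col)/l_lambda)
                + lambda_bulk

with ``y_col`` the closest wall distance accessible to the colloid centre
(one particle radius by default).  This module evaluates the fields, the
kernel, its first two moments, and draws kernel samples; fields can be
parametric (the relaxation laws above) or tabulated per spatial bin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

__all__ = [
    "Geometry",
    "ProfileParams",
    "ActivityField",
    "ParametricField",
    "TabulatedField",
    "eval_lambda",
    "eval_L",
    "jump_kernel_density",
    "jump_kernel_cdf",
    "kernel_moments",
    "sample_jump",
    "rescale_rate_to_reference",
    "table1_field",
]


@dataclass(frozen=True)
class Geometry:
    """Channel cross-section geometry.

    The channel has full width ``2 * half_width``; positions across the
    channel are measured either as absolute coordinates ``Y`` in
    ``[0, 2W]`` or, after folding about the axis, as the distance
    ``y = min(Y, 2W - Y)`` from the nearest wall.  The colloid centre can
    approach a wall no closer than ``wall_offset`` (one particle radius
    unless stated otherwise), so the accessible range is
    ``y in [wall_offset, half_width]``.
    """

    half_width: float  # W, um
    colloid_radius: float = 5.0  # a, um
    wall_offset: float | None = None  # y_col, um; defaults to a

    def __post_init__(self):
        if self.wall_offset is None:
            object.__setattr__(self, "wall_offset", self.colloid_radius)
        if not (self.colloid_radius > 0):
            raise ValueError("colloid_radius must be > 0")
        if not (self.half_width > self.wall_offset >= 0):
            raise ValueError("require W > y_col >= 0")

    @property
    def y_col(self) -> float:
        return float(self.wall_offset)

    @property
    def width(self) -> float:
        """Full channel width 2W (um)."""
        return 2.0 * self.half_width

    def wall_distance(self, Y):
        """Fold an absolute cross-channel coordinate onto [0, W]."""
        Y = np.asarray(Y, dtype=float)
        return np.minimum(Y, self.width - Y)

    def y_bounds(self) -> tuple[float, float]:
        """Accessible absolute coordinates of the colloid centre."""
        return (self.y_col, self.width - self.y_col)


@dataclass(frozen=True)
class ProfileParams:
    """Parameters of the exponential-relaxation activity profiles.

    Lengths in um, rates in 1/s.  ``L_wall`` is the common wall value of
    both characteristic jump lengths and is conventionally held fixed at
    0.375 um when fitting.
    """

    L_bulk: float
    l_plus: float
    l_minus: float
    lambda_wall: float
    lambda_bulk: float
    l_lambda: float
    L_wall: float = 0.375
    y_col: float = 5.0

    def __post_init__(self):
        for name in ("L_bulk", "l_plus", "l_minus", "l_lambda", "L_wall"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if not (self.lambda_wall > 0 and self.lambda_bulk > 0):
            raise ValueError("rates must be > 0")
        if self.L_wall > self.L_bulk:
            raise ValueError("expected L_wall <= L_bulk (relaxation toward bulk)")
        if self.y_col < 0:
            raise ValueError("y_col must be >= 0")


def _check_positions(y):
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("positions must be finite")
    return y


class ActivityField:
    """Interface: lambda(y), L+(y), L-(y) on the folded coordinate.

    Positions below ``y_col`` are clamped to ``y_col`` (the colloid centre
    cannot sit closer to a wall); positions beyond the half-width are
    allowed, the profiles extrapolate smoothly toward their bulk values.
    """

    geometry: Geometry

    def lambda_at(self, y):  # pragma: no cover - interface
        raise NotImplementedError

    def L_plus_at(self, y):  # pragma: no cover - interface
        raise NotImplementedError

    def L_minus_at(self, y):  # pragma: no cover - interface
        raise NotImplementedError

    def bulk_L(self) -> float:
        """Characteristic jump length far from the walls."""
        raise NotImplementedError

    def bulk_lambda(self) -> float:
        raise NotImplementedError


class ParametricField(ActivityField):
    """Activity field defined by exponential relaxation profiles."""

    def __init__(self, params: ProfileParams, geometry: Geometry):
        self.params = params
        self.geometry = geometry

    def _excess(self, y):
        y = _check_positions(y)
        return np.maximum(y, self.params.y_col) - self.params.y_col

    def lambda_at(self, y):
        p = self.params
        return (p.lambda_wall - p.lambda_bulk) * np.exp(-self._excess(y) / p.l_lambda) + p.lambda_bulk

    def L_plus_at(self, y):
        p = self.params
        return (p.L_wall - p.L_bulk) * np.exp(-self._excess(y) / p.l_plus) + p.L_bulk

    def L_minus_at(self, y):
        p = self.params
        return (p.L_wall - p.L_bulk) * np.exp(-self._excess(y) / p.l_minus) + p.L_bulk

    def bulk_L(self) -> float:
        return self.params.L_bulk

    def bulk_lambda(self) -> float:
        return self.params.lambda_bulk

    # Analytic d/dy of the three profiles; used by the continuum layer.
    def dlambda_at(self, y):
        p = self.params
        d = -(p.lambda_wall - p.lambda_bulk) / p.l_lambda * np.exp(-self._excess(y) / p.l_lambda)
        return np.where(np.asarray(y, float) < p.y_col, 0.0, d)

    def dL_plus_at(self, y):
        p = self.params
        d = -(p.L_wall - p.L_bulk) / p.l_plus * np.exp(-self._excess(y) / p.l_plus)
        return np.where(np.asarray(y, float) < p.y_col, 0.0, d)

    def dL_minus_at(self, y):
        p = self.params
        d = -(p.L_wall - p.L_bulk) / p.l_minus * np.exp(-self._excess(y) / p.l_minus)
        return np.where(np.asarray(y, float) < p.y_col, 0.0, d)

    def with_params(self, **kwargs) -> "ParametricField":
        return ParametricField(replace(self.params, **kwargs), self.geometry)


class TabulatedField(ActivityField):
    """Activity field given per spatial bin, linearly interpolated."""

    def __init__(self, y_centres, lam, L_plus, L_minus, geometry: Geometry):
        y_centres = np.asarray(y_centres, float)
        order = np.argsort(y_centres)
        self.y_centres = y_centres[order]
        self.lam = np.asarray(lam, float)[order]
        self.Lp = np.asarray(L_plus, float)[order]
        self.Lm = np.asarray(L_minus, float)[order]
        if np.any(self.lam <= 0) or np.any(self.Lp <= 0) or np.any(self.Lm <= 0):
            raise ValueError("tabulated rates and lengths must be > 0")
        self.geometry = geometry

    def _clamp(self, y):
        y = _check_positions(y)
        return np.maximum(y, self.geometry.y_col)

    def lambda_at(self, y):
        return np.interp(self._clamp(y), self.y_centres, self.lam)

    def L_plus_at(self, y):
        return np.interp(self._clamp(y), self.y_centres, self.Lp)

    def L_minus_at(self, y):
        return np.interp(self._clamp(y), self.y_centres, self.Lm)

    def bulk_L(self) -> float:
        return float(0.5 * (self.Lp[-1] + self.Lm[-1]))

    def bulk_lambda(self) -> float:
        return float(self.lam[-1])


def eval_lambda(field: ActivityField, y):
    """Jump (encounter) rate lambda(y) in 1/s at wall distance y (um)."""
    return field.lambda_at(y)


def eval_L(field: ActivityField, y, sign: Literal["away", "toward"]):
    """Characteristic jump length (um) at wall distance y.

    ``sign="away"`` selects L+ (jumps directed away from the wall),
    ``sign="toward"`` selects L-.
    """
    if sign == "away":
        return field.L_plus_at(y)
    if sign == "toward":
        return field.L_minus_at(y)
    raise ValueError(f"unknown sign tag {sign!r}; use 'away' or 'toward'")


def jump_kernel_density(field: ActivityField, y, y_J):
    """Density q_y(y_J) (1/um) of the wall-normal jump projection.

    Two-sided exponential: positive projections decay with L+(y), negative
    with L-(y); the common prefactor 1/(L+ + L-) normalises the density
    over the whole real line.
    """
    Lp = field.L_plus_at(y)
    Lm = field.L_minus_at(y)
    y_J = np.asarray(y_J, dtype=float)
    scale = np.where(y_J >= 0, Lp, Lm)
    return np.exp(-np.abs(y_J) / scale) / (Lp + Lm)


def jump_kernel_cdf(field: ActivityField, y, y_J):
    """CDF of the jump projection kernel q_y at wall distance y."""
    Lp = np.asarray(field.L_plus_at(y), float)
    Lm = np.asarray(field.L_minus_at(y), float)
    y_J = np.asarray(y_J, dtype=float)
    w_minus = Lm / (Lp + Lm)
    neg = w_minus * np.exp(np.minimum(y_J, 0.0) / Lm)
    pos = 1.0 - (1.0 - w_minus) * np.exp(-np.maximum(y_J, 0.0) / Lp)
    return np.where(y_J <= 0, neg, pos)


def kernel_moments(field: ActivityField, y, order: int):
    """Closed-form moments of q_y: m1 = L+ - L-, m2 = 2 (L+^3 + L-^3)/(L+ + L-)."""
    Lp = field.L_plus_at(y)
    Lm = field.L_minus_at(y)
    if order == 1:
        return Lp - Lm
    if order == 2:
        return 2.0 * (Lp**3 + Lm**3) / (Lp + Lm)
    raise ValueError("only moments of order 1 and 2 are defined")


def sample_jump(field: ActivityField, y, rng: np.random.Generator, size=None):
    """Draw signed jump projections y_J ~ q_y by inverse-transform sampling.

    The sign is positive (away from the wall) with probability
    L+/(L+ + L-); the magnitude is exponential with the matching scale.
    """
    Lp = np.asarray(field.L_plus_at(y), float)
    Lm = np.asarray(field.L_minus_at(y), float)
    if size is None:
        size = np.broadcast(Lp, Lm).shape or None
    p_plus = Lp / (Lp + Lm)
    away = rng.random(size) < p_plus
    scale = np.where(away, Lp, Lm)
    mag = rng.exponential(1.0, size) * scale
    return np.where(away, mag, -mag)


def rescale_rate_to_reference(lam, cell_concentration: float, reference_concentration: float):
    """Rescale encounter rates measured at one algal concentration to a reference.

    In the dilute regime the encounter rate is linear in swimmer density,
    so ``lam_ref = lam * reference / actual``.
    """
    if not (cell_concentration > 0 and reference_concentration > 0):
        raise ValueError("concentrations must be > 0")
    return np.asarray(lam, float) * (reference_concentration / cell_concentration)


def table1_field() -> ParametricField:
    """The packaged fitted activity field for the 100 um-wide channel."""
    from . import io  # local import to avoid a cycle

    from importlib.resources import files

    path = files("colloidjump.data").joinpath("channel100_profile.cfg")
    params, geometry = io.parse_profile_config(path.read_text())
    return ParametricField(params, geometry)
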