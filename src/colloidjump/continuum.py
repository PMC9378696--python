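"""Continuum description of the colloid density across the channel.

Three levels, all on the folded coordinate y in [y_col, W]:

1. The nonlocal master equation for the density P_t(y),

       dP/dt = D0 d2P/dy2 - lambda(y) P
               + Integral lambda(y - y_J) P(y - y_J) q_{y - y_J}(y_J) dy_J,

   discretized with a per-cell jump redistribution matrix.  Kernel mass
   that would land beyond a wall is assigned to the boundary cell (the
   stopping rule of the stochastic simulator); mass crossing the channel
   axis is folded back by symmetry.

2. Its Kramers-Moyal reduction, truncated at second order, a
   drift-diffusion equation with

       D_eff(y) = D0 + lambda(y) m2(y) / 2
       V_eff(y) = lambda(y) m1(y) - (1/2) d/dy [lambda(y) m2(y)]

   where m1 = L+ - L- and m2 = 2 (L+^3 + L-^3)/(L+ + L-) are the first
   two moments of the jump kernel.  The truncation is valid when the
   typical jump size is small compared to the scale of the spatial
   heterogeneity of the profiles.

3. The no-flux steady state in closed form,

       P(y) = B / D_eff(y) * exp( Integral^y lambda m1 / D_eff dy' ),

   and mean first-passage times of the effective dynamics.  For the
   Fokker-Planck form d/dy [D dP/dy - V P] the equivalent Ito drift is
   b = V_eff + dD_eff/dy, which reduces exactly to lambda(y) m1(y); the
   MFPT quadrature below uses it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid, trapezoid

from .profiles import ActivityField, ParametricField, jump_kernel_cdf, kernel_moments

__all__ = [
    "EffectiveFields",
    "ContinuumSolution",
    "effective_fields",
    "steady_state",
    "master_equation_propagate",
    "mfpt",
    "bin_masses",
]


@dataclass
class EffectiveFields:
    """Effective drift-diffusion fields of the coarse-grained dynamics."""

    grid: np.ndarray  # y values (um)
    D_eff: np.ndarray  # um^2/s
    V_eff: np.ndarray  # um/s
    lam_m1: np.ndarray  # lambda(y) m1(y): the Ito drift (um/s)
    D0: float

    def __post_init__(self):
        if np.any(self.D_eff <= 0):
            raise ValueError("D_eff must be positive everywhere")


@dataclass
class ContinuumSolution:
    """Discretized steady-state density with normalization metadata."""

    grid: np.ndarray
    P: np.ndarray  # density, 1/um; trapezoidal integral 1
    B: float  # normalization constant of the closed form
    flux_residual: float  # max |V_eff P - D_eff dP/dy| / max |V_eff P|


def effective_fields(
    field: ActivityField,
    D0: float,
    grid,
    derivative: str = "auto",
) -> EffectiveFields:
    """Evaluate D_eff and V_eff on a grid.

    ``derivative`` selects how d/dy[lambda m2] is computed: "analytic"
    (parametric fields only), "numeric" (centred differences, one-sided at
    the edges) or "auto" (analytic when available).  A grid coarser than a
    tenth of the shortest profile decay length triggers a warning since
    the numeric derivative then under-resolves the wall region.
    """
    grid = np.asarray(grid, float)
    if grid.ndim != 1 or grid.size < 3:
        raise ValueError("grid must be 1D with at least 3 points")
    h = np.diff(grid)
    lam = np.asarray(field.lambda_at(grid), float)
    m1 = np.asarray(kernel_moments(field, grid, 1), float)
    m2 = np.asarray(kernel_moments(field, grid, 2), float)
    lam_m2 = lam * m2
    use_analytic = derivative == "analytic" or (
        derivative == "auto" and isinstance(field, ParametricField)
    )
    if use_analytic:
        if not isinstance(field, ParametricField):
            raise ValueError("analytic derivatives require a ParametricField")
        Lp = np.asarray(field.L_plus_at(grid), float)
        Lm = np.asarray(field.L_minus_at(grid), float)
        dLp = np.asarray(field.dL_plus_at(grid), float)
        dLm = np.asarray(field.dL_minus_at(grid), float)
        dlam = np.asarray(field.dlambda_at(grid), float)
        S = Lp + Lm
        dm2_dLp = 6.0 * Lp**2 / S - m2 / S
        dm2_dLm = 6.0 * Lm**2 / S - m2 / S
        dm2 = dm2_dLp * dLp + dm2_dLm * dLm
        d_lam_m2 = dlam * m2 + lam * dm2
    else:
        import warnings

        min_l = _shortest_scale(field)
        if min_l is not None and np.max(h) > min_l / 10.0:
            warnings.warn(
                f"grid spacing {np.max(h):.3g} um is coarse for the shortest decay "
                f"length {min_l:.3g} um; refine to at most {min_l / 10.0:.3g} um"
            )
        d_lam_m2 = np.gradient(lam_m2, grid)
    D_eff = D0 + lam_m2 / 2.0
    V_eff = lam * m1 - 0.5 * d_lam_m2
    return EffectiveFields(grid=grid, D_eff=D_eff, V_eff=V_eff, lam_m1=lam * m1, D0=D0)


def _shortest_scale(field: ActivityField):
    if isinstance(field, ParametricField):
        p = field.params
        return min(p.l_plus, p.l_minus, p.l_lambda)
    return None


def steady_state(fields: EffectiveFields) -> ContinuumSolution:
    """Closed-form no-flux steady state P = (B / D_eff) exp(int lam m1 / D_eff).

    The exponent integral runs from the wall-side end of the grid (the
    choice of reference point is absorbed into B); B is fixed by
    trapezoidal normalization over the grid.
    """
    y = fields.grid
    expo = cumulative_trapezoid(fields.lam_m1 / fields.D_eff, y, initial=0.0)
    expo -= expo.max()  # overflow guard; rescaling is absorbed into B
    raw = np.exp(expo) / fields.D_eff
    Z = trapezoid(raw, y)
    P = raw / Z
    B = 1.0 / Z * np.exp(-0.0)
    # flux diagnostic on the staggered midpoint grid: centred differences
    # everywhere (one-sided edge stencils would dominate the residual in
    # the steep wall boundary layer)
    h = np.diff(y)
    VP = fields.V_eff * P
    J_mid = 0.5 * (VP[1:] + VP[:-1]) - 0.5 * (fields.D_eff[1:] + fields.D_eff[:-1]) * np.diff(P) / h
    denom = np.max(np.abs(VP))
    resid = float(np.max(np.abs(J_mid)) / denom) if denom > 0 else float(np.max(np.abs(J_mid)))
    return ContinuumSolution(grid=y, P=P, B=float(B), flux_residual=resid)


def _jump_matrix(field: ActivityField, edges: np.ndarray, centres: np.ndarray, W: float):
    """K[j, i]: probability that a jump starting in cell i lands in cell j.

    Landing positions below the wall offset stop there (boundary cell 0);
    positions beyond the channel axis W fold back by symmetry, and the
    fold of the far-wall stopping point is again cell 0.
    """
    n = centres.size
    ylo = edges[0]
    K = np.empty((n, n))
    for i in range(n):
        yi = centres[i]
        cdf_direct = np.asarray(jump_kernel_cdf(field, yi, edges - yi), float)
        direct = np.diff(cdf_direct)
        # mass below the wall -> stopped at the wall cell
        wall_mass = cdf_direct[0]
        # mass landing beyond W folds back: position z > W maps to 2W - z,
        # so folded cell [e_j, e_j+1] collects z in [2W - e_j+1, 2W - e_j]
        cdf_hi = np.asarray(jump_kernel_cdf(field, yi, (2.0 * W - edges) - yi), float)
        folded = cdf_hi[:-1] - cdf_hi[1:]
        # beyond the far wall: stopped at 2W - ylo, folds to the wall cell
        far_mass = 1.0 - cdf_hi[0]
        K[:, i] = direct + folded
        K[0, i] += wall_mass + far_mass
    return K


def master_equation_propagate(
    field: ActivityField,
    D0: float,
    P0,
    grid,
    dt: float,
    n_steps: int,
    return_diagnostics: bool = False,
):
    """Explicit time stepping of the discretized master equation.

    ``grid`` must be uniform; ``P0`` is a density on it (normalized
    internally).  Diffusion uses a no-flux explicit stencil, jumps the
    precomputed redistribution matrix.  Raises on a CFL-unstable ``dt``
    or if negative mass beyond round-off appears.  Returns the final
    density (and, optionally, diagnostics with the maximum per-step mass
    defect).
    """
    grid = np.asarray(grid, float)
    h = grid[1] - grid[0]
    if not np.allclose(np.diff(grid), h):
        raise ValueError("master-equation grid must be uniform")
    if D0 > 0 and D0 * dt / h**2 > 0.5:
        raise ValueError(f"CFL violation: D0*dt/h^2 = {D0 * dt / h**2:.3g} > 0.5")
    lam = np.asarray(field.lambda_at(grid), float)
    if np.max(lam) * dt > 1.0:
        raise ValueError("lambda * dt exceeds 1")
    W = field.geometry.half_width
    edges = np.concatenate([[grid[0] - h / 2.0], grid + h / 2.0])
    K = _jump_matrix(field, edges, grid, W)

    p = np.asarray(P0, float) * h  # cell masses
    total0 = p.sum()
    if total0 <= 0:
        raise ValueError("P0 must have positive mass")
    p = p / total0
    alpha = D0 * dt / h**2
    max_defect = 0.0
    for _ in range(n_steps):
        mass_before = p.sum()
        out = lam * dt * p
        p_new = p - out + K @ out
        if alpha > 0:
            lap = np.empty_like(p)
            lap[1:-1] = p[2:] - 2.0 * p[1:-1] + p[:-2]
            lap[0] = p[1] - p[0]
            lap[-1] = p[-2] - p[-1]
            p_new = p_new + alpha * lap
        defect = abs(p_new.sum() - mass_before)
        max_defect = max(max_defect, defect)
        if p_new.min() < -1e-9:
            raise RuntimeError("instability detected: negative mass beyond tolerance")
        p = p_new
    P = p / h
    if return_diagnostics:
        return P, {"max_step_mass_defect": max_defect, "final_mass": float(p.sum())}
    return P


def mfpt(fields: EffectiveFields, start_y, absorbing: str = "lower"):
    """Mean first-passage time (s) of the effective dynamics.

    One end of the grid is absorbing, the other reflecting.  Uses the
    standard double quadrature for the backward equation
    D T'' + b T' = -1 with the Ito drift b = lambda m1:

        T(y) = int_a^y exp(-Phi(s)) [ int_s^r exp(Phi(u)) / D(u) du ] ds,
        Phi(s) = int_a^s b/D du,

    with a the absorbing and r the reflecting end.  ``start_y`` may be a
    scalar or an array; values are interpolated on the grid.
    """
    y = fields.grid
    D = fields.D_eff
    b = fields.lam_m1
    if absorbing == "upper":
        # mirror the domain so the absorber sits at the grid start
        yr = y[::-1].copy()
        T_rev = _mfpt_from_lower(-(yr - yr[0]), D[::-1], -b[::-1])
        T_grid = T_rev[::-1]
    elif absorbing == "lower":
        T_grid = _mfpt_from_lower(y, D, b)
    else:
        raise ValueError("absorbing must be 'lower' or 'upper'")
    start_y = np.asarray(start_y, float)
    if y[0] >= y[-1]:
        raise ValueError("degenerate interval")
    out = np.interp(start_y, y, T_grid)
    return float(out) if out.ndim == 0 else out


def _mfpt_from_lower(y, D, b):
    Phi = cumulative_trapezoid(b / D, y, initial=0.0)
    Phi -= Phi.max()
    psi = np.exp(Phi)
    inner_full = cumulative_trapezoid(psi / D, y, initial=0.0)
    inner = inner_full[-1] - inner_full  # int_s^r psi/D
    integrand = inner / psi
    return cumulative_trapezoid(integrand, y, initial=0.0)


def bin_masses(solution: ContinuumSolution, edges) -> np.ndarray:
    """Integrate the steady-state density over histogram bins.

    Returns probability masses per bin (sums to ~1 when the edges cover
    the grid), for direct comparison with simulated histograms.
    """
    edges = np.asarray(edges, float)
    y = solution.grid
    P = solution.P
    cum = cumulative_trapezoid(P, y, initial=0.0)
    at_edges = np.interp(edges, y, cum)
    return np.diff(at_edges)
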