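"""Estimation of the activity profiles from detected jump events.

Per spatial bin the encounter rate comes from an affine fit to the
logarithm of the waiting-time histogram restricted to the exponential
tail (waits above ``t_min``; shorter waits are contaminated by rapid
repeat encounters with the same swimmer), and the characteristic jump
lengths from affine fits to the logarithm of each side of the y_J
histogram inside a window ``min_cut < |y_J| < lim(y)`` (the window
excludes sub-resolution moves and the slower-than-exponential positive
tails that appear close to the wall).  The binned estimates are then
reduced to the exponential relaxation laws by weighted nonlinear least
squares with the wall length fixed.

Histogram regression (rather than maximum likelihood) is used on purpose:
its behaviour under window truncation is what defines the characteristic
length of the *initial* decay of the distributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit, least_squares

from .detection import DetectionParams, bin_by_wall_distance, default_bin_edges, detect_jumps, waiting_times
from .profiles import Geometry, ProfileParams

__all__ = [
    "FitValue",
    "BinFitResult",
    "fit_waiting_rate",
    "fit_jump_lengths",
    "table2_limits",
    "bin_fit",
    "fit_profiles",
    "estimate_profiles",
]


@dataclass(frozen=True)
class FitValue:
    value: float
    se: float


@dataclass
class BinFitResult:
    y_centre: float
    lam: FitValue | None  # None marks a flagged-missing estimate
    L_plus: FitValue | None
    L_minus: FitValue | None
    n_waits: int
    n_jumps: int
    lim: float
    t_min: float


def _affine_logcounts(centres, counts):
    """Weighted affine fit of log(counts) vs centres; returns (slope, SE).

    Weights are the counts themselves: for Poisson bin counts the variance
    of log N is ~1/N, so this is the proper GLS weighting and it keeps the
    nearly-empty far-tail bins (whose zero-truncated logs would otherwise
    flatten the slope) from biasing the fit.
    """
    keep = counts > 0
    x = centres[keep]
    w = counts[keep].astype(float)
    z = np.log(w)
    if x.size < 3:
        return None
    n = x.size
    sw = w.sum()
    xm = np.sum(w * x) / sw
    zm = np.sum(w * z) / sw
    sxx = np.sum(w * (x - xm) ** 2)
    slope = np.sum(w * (x - xm) * (z - zm)) / sxx
    resid = z - (zm + slope * (x - xm))
    dof = max(n - 2, 1)
    chi2 = np.sum(w * resid**2) / dof  # reduced chi^2 under Var(log N) = 1/N
    se = np.sqrt(max(chi2, 1.0) / sxx)
    return slope, se


def fit_waiting_rate(
    waits,
    t_min: float = 3.0,
    bin_width: float = 0.5,
    method: str = "survival",
    min_samples: int = 10,
) -> FitValue | None:
    """Encounter rate (1/s) from the exponential tail of waiting times.

    Returns None (flagged missing) when fewer than ``min_samples`` waits
    exceed ``t_min`` or the tail slope is not a decay.  ``method`` selects
    an affine regression of the log empirical survival function over the
    tail (default; unbiased at the per-bin sample sizes this pipeline
    produces) or of the log-histogram (whose zero-truncated far-tail bins
    bias the slope low unless the tail is sampled very densely).  The
    reported SE is floored at the asymptotic exponential-tail value
    rate/sqrt(n_tail), since the survival-regression residuals are
    strongly autocorrelated and their OLS SE is over-optimistic.
    """
    waits = np.asarray(waits, float)
    tail = waits[waits > t_min]
    if tail.size < min_samples:
        return None
    if method == "survival":
        t_sorted = np.sort(tail)
        surv = 1.0 - (np.arange(t_sorted.size) + 0.5) / t_sorted.size
        z = np.log(surv)
        x = t_sorted
        xm = x.mean()
        sxx = np.sum((x - xm) ** 2)
        slope = np.sum((x - xm) * (z - z.mean())) / sxx
        resid = z - (z.mean() + slope * (x - xm))
        se = np.sqrt(np.sum(resid**2) / max(x.size - 2, 1) / sxx)
        fit = (slope, se)
    elif method == "histogram":
        edges = np.arange(t_min, tail.max() + bin_width, bin_width)
        if edges.size < 4:
            return None
        counts, edges = np.histogram(tail, bins=edges)
        centres = 0.5 * (edges[:-1] + edges[1:])
        fit = _affine_logcounts(centres, counts.astype(float))
    else:
        raise ValueError("method must be 'histogram' or 'survival'")
    if fit is None:
        return None
    slope, se = fit
    if slope >= 0:
        return None
    rate = -slope
    se = max(se, rate / np.sqrt(tail.size))
    return FitValue(value=rate, se=se)


def fit_jump_lengths(
    y_J,
    lim: float,
    min_cut: float = 1.0,
    bin_width: float = 1.0,
    min_samples: int = 10,
) -> tuple[FitValue | None, FitValue | None]:
    """(L+, L-) from affine fits to the log-histogram of each side of y_J.

    Only samples with ``min_cut < |y_J| < lim`` enter each side's fit; an
    empty or too-small side is flagged as None.
    """
    y_J = np.asarray(y_J, float)
    out = []
    for sign in (+1.0, -1.0):
        mag = sign * y_J[sign * y_J > 0]
        mag = mag[(mag > min_cut) & (mag < lim)]
        if mag.size < min_samples:
            out.append(None)
            continue
        edges = np.arange(min_cut, lim + 1e-9, bin_width)
        if edges.size < 4:
            edges = np.linspace(min_cut, lim, 4)
        counts, edges = np.histogram(mag, bins=edges)
        centres = 0.5 * (edges[:-1] + edges[1:])
        fit = _affine_logcounts(centres, counts.astype(float))
        if fit is None or fit[0] >= 0:
            out.append(None)
            continue
        slope, se = fit
        L = -1.0 / slope
        out.append(FitValue(value=L, se=se / slope**2))
    return out[0], out[1]


def table2_limits(bin_centres) -> np.ndarray:
    """Standard |y_J| fit limits per wall-distance bin (um).

    7 um in the first bin, then 12, 12, 15, 15, 18 and 20 um from the
    seventh bin outward: the window grows with distance from the wall as
    the distributions become exponential over a longer range.
    """
    base = [7.0, 12.0, 12.0, 15.0, 15.0, 18.0]
    n = len(np.asarray(bin_centres))
    return np.array([base[i] if i < len(base) else 20.0 for i in range(n)])


def bin_fit(
    jump_y,
    jump_yJ,
    wait_y,
    waits,
    edges,
    t_min: float = 3.0,
    lims=None,
    min_cut: float = 1.0,
) -> list[BinFitResult]:
    """Per-bin estimates of lambda, L+ and L- from pooled event samples."""
    edges = np.asarray(edges, float)
    centres = 0.5 * (edges[:-1] + edges[1:])
    if lims is None:
        lims = table2_limits(centres)
    jidx, _ = bin_by_wall_distance(jump_y, edges)
    widx, _ = bin_by_wall_distance(wait_y, edges)
    jump_yJ = np.asarray(jump_yJ, float)
    waits = np.asarray(waits, float)
    results = []
    for b, yc in enumerate(centres):
        yJ_b = jump_yJ[jidx == b]
        w_b = waits[widx == b]
        Lp, Lm = fit_jump_lengths(yJ_b, lim=float(lims[b]), min_cut=min_cut)
        lam = fit_waiting_rate(w_b, t_min=t_min)
        results.append(
            BinFitResult(
                y_centre=float(yc),
                lam=lam,
                L_plus=Lp,
                L_minus=Lm,
                n_waits=int(w_b.size),
                n_jumps=int(yJ_b.size),
                lim=float(lims[b]),
                t_min=t_min,
            )
        )
    return results


def _usable(bins, attr):
    pts = [(b.y_centre, getattr(b, attr)) for b in bins if getattr(b, attr) is not None]
    y = np.array([p[0] for p in pts])
    v = np.array([p[1].value for p in pts])
    se = np.array([max(p[1].se, 1e-12) for p in pts])
    return y, v, se


def fit_profiles(
    bins: list[BinFitResult],
    y_col: float,
    L_wall: float = 0.375,
) -> tuple[ProfileParams, dict]:
    """Weighted NLS of the exponential relaxation laws to binned estimates.

    L+ and L- are fitted jointly with a shared bulk length and the wall
    value fixed at ``L_wall``; lambda(y) is fitted separately with three
    free parameters.  Initial values come from endpoint heuristics (wall
    bin and the mean of the outermost three bins), so starts are
    deterministic.  Returns the fitted :class:`ProfileParams` and a dict
    of standard errors.
    """
    yp, Lp, sp = _usable(bins, "L_plus")
    ym, Lm, sm = _usable(bins, "L_minus")
    yl, lam, sl = _usable(bins, "lam")
    if min(yp.size, ym.size, yl.size) < 4:
        raise ValueError("need at least 4 usable bins per curve")

    L_bulk0 = float(np.mean(np.concatenate([Lp[-3:], Lm[-3:]])))
    x0 = np.array([max(L_bulk0, L_wall + 0.1), 8.0, 8.0])

    def resid_L(p):
        L_bulk, l_plus, l_minus = p
        mp = (L_wall - L_bulk) * np.exp(-(yp - y_col) / l_plus) + L_bulk
        mm = (L_wall - L_bulk) * np.exp(-(ym - y_col) / l_minus) + L_bulk
        return np.concatenate([(mp - Lp) / sp, (mm - Lm) / sm])

    sol = least_squares(resid_L, x0, bounds=([L_wall, 0.1, 0.1], [np.inf] * 3))
    if not sol.success:
        raise RuntimeError(f"L± profile fit did not converge: {sol.message}")
    L_bulk, l_plus, l_minus = sol.x
    se_L = _lsq_se(sol)

    lam_w0 = float(lam[np.argmin(yl)])
    lam_b0 = float(np.mean(lam[-3:]))

    def lam_model(y, lam_w, lam_b, l_lam):
        return (lam_w - lam_b) * np.exp(-(y - y_col) / l_lam) + lam_b

    popt, pcov = curve_fit(
        lam_model,
        yl,
        lam,
        p0=[lam_w0, lam_b0, 8.0],
        sigma=sl,
        absolute_sigma=False,
        bounds=([1e-6, 1e-6, 0.1], [np.inf] * 3),
        maxfev=20000,
    )
    lam_w, lam_b, l_lam = popt
    se_lam = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))

    params = ProfileParams(
        L_bulk=float(L_bulk),
        l_plus=float(l_plus),
        l_minus=float(l_minus),
        lambda_wall=float(lam_w),
        lambda_bulk=float(lam_b),
        l_lambda=float(l_lam),
        L_wall=L_wall,
        y_col=y_col,
    )
    errors = {
        "L_bulk": se_L[0],
        "l_plus": se_L[1],
        "l_minus": se_L[2],
        "lambda_wall": float(se_lam[0]),
        "lambda_bulk": float(se_lam[1]),
        "l_lambda": float(se_lam[2]),
    }
    return params, errors


def _lsq_se(sol):
    """Parameter SEs from a scipy least_squares solution (Gauss-Newton cov)."""
    _, s, VT = np.linalg.svd(sol.jac, full_matrices=False)
    s = np.where(s > 1e-12 * s[0], s, np.inf)
    cov = (VT.T / s**2) @ VT
    dof = max(sol.fun.size - sol.x.size, 1)
    cov = cov * 2.0 * sol.cost / dof
    return np.sqrt(np.clip(np.diag(cov), 0, np.inf))


def estimate_profiles(
    trajectories,
    geometry: Geometry,
    D0: float,
    params: DetectionParams | None = None,
    edges=None,
    t_min: float = 3.0,
    min_cut: float = 1.0,
    L_wall: float = 0.375,
):
    """End-to-end pipeline: detect jumps, pool samples, bin, fit profiles.

    Returns ``(profile_params, errors, bins)``.
    """
    if params is None:
        params = DetectionParams()
    if edges is None:
        edges = default_bin_edges(geometry)
    jump_y, jump_yJ, wait_y, waits = [], [], [], []
    for traj in trajectories:
        events = detect_jumps(traj, geometry, params, D0)
        jump_y.extend(e.y0 for e in events)
        jump_yJ.extend(e.y_J for e in events)
        wy, w = waiting_times(events, traj, geometry)
        wait_y.extend(wy)
        waits.extend(w)
    bins = bin_fit(jump_y, jump_yJ, wait_y, waits, edges, t_min=t_min, min_cut=min_cut)
    profile, errors = fit_profiles(bins, y_col=geometry.y_col, L_wall=L_wall)
    return profile, errors, bins
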