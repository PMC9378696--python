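"""Two-compartment first-order kinetics of colloid de-mixing.

Colloids transition from a main chamber into narrow side channels (which
the swimmers cannot enter) at rate ``k_in`` and back out at ``k_out``.
With conserved total count N_t the side-channel occupancy relaxes
exponentially,

    N_s(t) = N_s_inf + (N_s(0) - N_s_inf) exp(-(k_in + k_out) t),
    N_s_inf = N_t k_in / (k_in + k_out),

with time scale tau = 1/(k_in + k_out) and stationary fractions
k_out/(k_in + k_out) (chamber) and k_in/(k_in + k_out) (side channels).
Times are seconds internally; reports convert to minutes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = ["KineticRates", "kinetics_solution", "rates_from_relaxation", "fit_kinetics", "demixed_fraction"]


@dataclass
class KineticRates:
    k_in: float  # 1/s
    k_out: float  # 1/s
    k_in_se: float = 0.0
    k_out_se: float = 0.0

    def __post_init__(self):
        if self.k_in < 0 or self.k_out < 0:
            raise ValueError("rates must be >= 0")

    @property
    def tau(self) -> float:
        """Relaxation time 1/(k_in + k_out), s."""
        return 1.0 / (self.k_in + self.k_out)

    @property
    def tau_min(self) -> float:
        return self.tau / 60.0

    @property
    def chamber_fraction(self) -> float:
        return self.k_out / (self.k_in + self.k_out)

    @property
    def side_fraction(self) -> float:
        return self.k_in / (self.k_in + self.k_out)


def kinetics_solution(k_in: float, k_out: float, N_t: float, N_s0: float, t):
    """Exact occupancies (N_c, N_s) at times t (s) for given rates (1/s)."""
    if k_in < 0 or k_out < 0:
        raise ValueError("rates must be >= 0")
    t = np.asarray(t, float)
    k = k_in + k_out
    if k == 0:
        N_s = np.full_like(t, float(N_s0))
    else:
        N_s_inf = N_t * k_in / k
        N_s = N_s_inf + (N_s0 - N_s_inf) * np.exp(-k * t)
    return N_t - N_s, N_s


def rates_from_relaxation(tau_s: float, side_fraction: float) -> KineticRates:
    """Invert (tau, stationary side fraction) into (k_in, k_out)."""
    if tau_s <= 0 or not (0 <= side_fraction <= 1):
        raise ValueError("invalid relaxation parameters")
    k = 1.0 / tau_s
    return KineticRates(k_in=side_fraction * k, k_out=(1.0 - side_fraction) * k)


def fit_kinetics(
    t,
    N_c,
    N_s,
    conservation_tol: float = 0.05,
) -> KineticRates:
    """Nonlinear LS fit of the first-order kinetics to an occupancy series.

    The fit runs on N_s(t) (the monotone observable, starting near zero)
    with the total count fixed to its time average; an N_t drift beyond
    ``conservation_tol`` (relative) raises, since conserved particle
    number is an assumption of the two-compartment model.
    """
    t = np.asarray(t, float)
    N_c = np.asarray(N_c, float)
    N_s = np.asarray(N_s, float)
    if t.size < 5:
        raise ValueError("need at least 5 time points")
    N_tot = N_c + N_s
    N_t = float(N_tot.mean())
    if N_t <= 0:
        raise ValueError("empty system")
    drift = np.max(np.abs(N_tot - N_t)) / N_t
    if drift > conservation_tol:
        raise ValueError(f"total particle number drifts by {drift:.1%} (> {conservation_tol:.0%})")
    N_s0 = float(N_s[0])

    if np.allclose(N_s, 0.0):
        # nothing ever enters the side channels: k_in is zero and k_out is
        # unidentifiable from this series
        return KineticRates(k_in=0.0, k_out=0.0, k_in_se=0.0, k_out_se=float("inf"))

    def model(tt, k_in, k_out):
        return kinetics_solution(k_in, k_out, N_t, N_s0, tt)[1]

    span = max(t[-1] - t[0], 1.0)
    f_inf = min(max(N_s[-1] / N_t, 0.02), 0.98)
    k0 = 3.0 / span
    p0 = [f_inf * k0, (1.0 - f_inf) * k0]
    popt, pcov = curve_fit(model, t, N_s, p0=p0, bounds=([0.0, 0.0], [np.inf, np.inf]), maxfev=20000)
    se = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
    # occupancy noise is a Markov process, so residuals are strongly
    # autocorrelated and the iid covariance is over-optimistic; inflate by
    # the AR(1) effective-sample-size factor sqrt((1+rho)/(1-rho))
    resid = N_s - model(t, *popt)
    if resid.size > 3 and np.any(resid != 0):
        r0 = float(np.var(resid))
        r1 = float(np.mean((resid[:-1] - resid.mean()) * (resid[1:] - resid.mean())))
        rho = min(max(r1 / r0, 0.0), 0.98) if r0 > 0 else 0.0
        se = se * np.sqrt((1.0 + rho) / (1.0 - rho))
    return KineticRates(k_in=float(popt[0]), k_out=float(popt[1]), k_in_se=float(se[0]), k_out_se=float(se[1]))


def demixed_fraction(k_active_in: float, k_reference_in: float) -> float:
    """Stationary de-mixed fraction k_in / (k_in + k_ref) of a two-chamber design.

    ``k_reference_in`` is the filling rate of the reference (passive-only)
    chamber; both zero is undefined.
    """
    if k_active_in < 0 or k_reference_in < 0:
        raise ValueError("rates must be >= 0")
    if k_active_in == 0 and k_reference_in == 0:
        raise ZeroDivisionError("both rates are zero")
    return k_active_in / (k_active_in + k_reference_in)
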