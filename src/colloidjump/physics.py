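"""Small physical-constant helpers.

The background (thermal) diffusivity of the colloids enters both the
synthetic generator and the simulator; it is fixed by the Stokes-Einstein
relation for a sphere in water rather than fitted.
"""

import math

BOLTZMANN = 1.380649e-23  # J/K


def water_viscosity(temperature_c: float) -> float:
    """Dynamic viscosity of water (Pa s), Vogel-Fulcher-Tammann correlation.

    eta = 2.414e-5 * 10^(247.8 / (T - 140)) with T in kelvin; accurate to
    ~1% between 0 and 100 degC.
    """
    T = temperature_c + 273.15
    return 2.414e-5 * 10.0 ** (247.8 / (T - 140.0))


def stokes_einstein_diffusivity(radius_um: float, temperature_c: float = 21.0) -> float:
    """Thermal diffusivity (um^2/s) of a sphere of given radius in water.

    D = kB T / (6 pi eta a).  For a 5 um-radius polystyrene bead at
    21 degC this gives ~0.044 um^2/s: the colloids are only weakly
    Brownian, so their transport is dominated by active jumps.
    """
    if radius_um <= 0:
        raise ValueError("radius must be > 0")
    T = temperature_c + 273.15
    eta = water_viscosity(temperature_c)
    D_m2_per_s = BOLTZMANN * T / (6.0 * math.pi * eta * radius_um * 1e-6)
    return D_m2_per_s * 1e12
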