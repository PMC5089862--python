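"""Unit conventions and physical constants.

The package works in a fixed unit system chosen to match coarse-grained
cytoplasm modelling practice:

* length        Angstrom (A)
* time          picosecond (ps)
* temperature   Kelvin
* energy        kBT (thermal units; energies are dimensionless multiples)
* charge        elementary charges
* diffusion     A^2/ps
* viscosity     mPa*s (= cP), only as an input parameter

All conversions to SI happen inside the helpers below.
"""

from __future__ import annotations

import math

#: Boltzmann constant [J/K]
KB_J = 1.380649e-23

#: elementary charge [C]
E_CHARGE = 1.602176634e-19

#: vacuum permittivity [F/m]
EPS0 = 8.8541878128e-12

#: m^2/s -> A^2/ps
_M2_PER_S_TO_A2_PER_PS = 1.0e8

#: default conditions (water at room temperature)
DEFAULT_TEMPERATURE = 298.0  # K
DEFAULT_VISCOSITY = 0.890    # mPa*s


def stokes_einstein_d(radius: float,
                      temperature: float = DEFAULT_TEMPERATURE,
                      viscosity: float = DEFAULT_VISCOSITY) -> float:
    """Dilute-limit translational diffusion constant kBT/(6 pi eta a).

    Parameters
    ----------
    radius : Stokes radius in A.
    temperature : K.
    viscosity : mPa*s.

    Returns
    -------
    float
        D in A^2/ps.
    """
    if radius <= 0:
        raise ValueError(f"radius must be positive, got {radius}")
    if temperature <= 0 or viscosity <= 0:
        raise ValueError("temperature and viscosity must be positive")
    d_si = KB_J * temperature / (6.0 * math.pi * viscosity * 1e-3 * radius * 1e-10)
    return d_si * _M2_PER_S_TO_A2_PER_PS


def stokes_einstein_drot(radius: float,
                         temperature: float = DEFAULT_TEMPERATURE,
                         viscosity: float = DEFAULT_VISCOSITY) -> float:
    """Dilute-limit rotational diffusion constant kBT/(8 pi eta a^3) in rad^2/ps."""
    if radius <= 0:
        raise ValueError(f"radius must be positive, got {radius}")
    d_si = KB_J * temperature / (8.0 * math.pi * viscosity * 1e-3 * (radius * 1e-10) ** 3)
    return d_si * 1e-12  # 1/s -> 1/ps


def bjerrum_length(temperature: float = DEFAULT_TEMPERATURE,
                   rel_permittivity: float = 80.0) -> float:
    """Bjerrum length e^2/(4 pi eps0 eps_r kBT) in A (~7.0 A in water at 298 K)."""
    lb_m = E_CHARGE ** 2 / (4.0 * math.pi * EPS0 * rel_permittivity * KB_J * temperature)
    return lb_m * 1e10
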