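"""Relativistic electron beam kinematics.

The accelerating potential V fixes everything the scattering calculation
needs to know about the beam: the Lorentz factor ``gamma = 1 + eV/(m0 c^2)``,
the velocity ratio ``beta = v/c = sqrt(1 - 1/gamma^2)`` and the relativistic
de Broglie wavelength ``lambda = h / sqrt(2 m0 e V (1 + eV / 2 m0 c^2))``.

Physical constants are CODATA 2018 values hard-coded at full published
precision, so results do not depend on the version of any constants library.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "PLANCK_H",
    "ELECTRON_MASS",
    "SPEED_OF_LIGHT",
    "ELEMENTARY_CHARGE",
    "ELECTRON_REST_ENERGY_EV",
    "COMPTON_WAVELENGTH_ANGSTROM",
    "BeamParameters",
    "beam_parameters",
    "voltage_from_gamma",
]

# CODATA 2018.  h, c and e are exact by the 2019 SI redefinition.
PLANCK_H = 6.62607015e-34  # J s
SPEED_OF_LIGHT = 299792458.0  # m / s
ELEMENTARY_CHARGE = 1.602176634e-19  # C
ELECTRON_MASS = 9.1093837015e-31  # kg
ELECTRON_REST_ENERGY_EV = 510998.95000  # eV
# h / (m0 c), the Compton wavelength, in Angstrom
COMPTON_WAVELENGTH_ANGSTROM = 1e10 * PLANCK_H / (ELECTRON_MASS * SPEED_OF_LIGHT)


@dataclass(frozen=True)
class BeamParameters:
    """Derived kinematic quantities for one accelerating voltage.

    Attributes
    ----------
    voltage : float
        Accelerating potential in volts.
    beta : float
        Velocity ratio v/c, dimensionless, in [0, 1).
    gamma : float
        Lorentz factor, dimensionless, >= 1.
    wavelength : float
        Relativistic electron wavelength in Angstrom (0.0 at rest).
    """

    voltage: float
    beta: float
    gamma: float
    wavelength: float


def beam_parameters(voltage: float) -> BeamParameters:
    """Compute relativistic beam parameters from the accelerating voltage.

    Parameters
    ----------
    voltage : float
        Accelerating potential in volts; must be non-negative.

    Returns
    -------
    BeamParameters

    Raises
    ------
    ValueError
        If *voltage* is negative.

    Examples
    --------
    >>> bp = beam_parameters(200e3)
    >>> round(bp.gamma, 5), round(bp.wavelength, 5)
    (1.39139, 0.02508)
    """
    v = float(voltage)
    if not math.isfinite(v) or v < 0:
        raise ValueError(f"accelerating voltage must be >= 0 V, got {voltage!r}")
    gamma = 1.0 + v / ELECTRON_REST_ENERGY_EV
    beta = math.sqrt(1.0 - 1.0 / (gamma * gamma))
    if v == 0.0:
        wavelength = 0.0
    else:
        # lambda = h / p; p^2 = 2 m0 eV (1 + eV / 2 m0 c^2) is numerically
        # stable for arbitrarily small V (no cancellation in gamma - 1)
        ev_joule = ELEMENTARY_CHARGE * v
        p = math.sqrt(
            2.0 * ELECTRON_MASS * ev_joule
            * (1.0 + v / (2.0 * ELECTRON_REST_ENERGY_EV))
        )
        # p underflows for denormally small voltages; the wavelength is
        # then beyond any physical relevance
        wavelength = 1e10 * PLANCK_H / p if p > 0.0 else math.inf
    return BeamParameters(voltage=v, beta=beta, gamma=gamma, wavelength=wavelength)


def voltage_from_gamma(gamma: float) -> float:
    """Invert the gamma(V) relation; used for round-trip consistency checks."""
    if gamma < 1.0:
        raise ValueError(f"gamma must be >= 1, got {gamma!r}")
    return (gamma - 1.0) * ELECTRON_REST_ENERGY_EV
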