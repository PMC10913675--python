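"""Fast evaluation of beta*f' from a parameter table, and the complex factor.

The stored quantity is the voltage-independent product beta*f'.  At a given
accelerating voltage the full complex scattering factor is::

    gamma f(s)  +  i gamma f'(s),      f' = (beta f') / beta

with gamma and beta from :func:`edafs.kinematics.beam_parameters`.

Because the node model is analytic in s, interpolation is needed only in
B_iso: the two node curves bracketing the requested B_iso are evaluated at
the exact s and combined linearly, negative values are clamped to zero, and
s beyond the fit domain (6 1/A) returns zero for the absorptive part (the
Born part stays analytic at any s).  Requests outside the table's B_iso
range raise instead of extrapolating: the surface is strongly curved in B
and silent extrapolation is unsafe for refinement codes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

from .born import atomic_number, born_factor, default_born_table
from .kinematics import beam_parameters
from .parameterization import ParameterTable

__all__ = [
    "S_MAX",
    "ComplexScatteringFactor",
    "beta_fprime_param",
    "complex_scattering_factor",
]

#: upper end of the fitted s domain; the absorptive part is defined as zero
#: beyond it (already negligible there under the temperature factor)
S_MAX = 6.0


@dataclass(frozen=True)
class ComplexScatteringFactor:
    """gamma*f + i*gamma*f' in Angstrom (arrays when s was an array)."""

    real: np.ndarray
    imag: np.ndarray

    @property
    def complex(self) -> np.ndarray:
        return self.real + 1j * self.imag


def _bracketing_nodes(table: ParameterTable, z: int, b_iso: float):
    grid = np.asarray(table.b_iso_grid)
    if not (grid[0] <= b_iso <= grid[-1]):
        raise ValueError(
            f"B_iso={b_iso} outside the table range [{grid[0]}, {grid[-1]}] A^2; "
            "refusing to extrapolate"
        )
    nodes = table.nodes(z)
    hi = int(np.searchsorted(grid, b_iso))
    if hi < len(grid) and grid[hi] == b_iso:
        return nodes[hi], nodes[hi], 0.0
    lo = hi - 1
    frac = (b_iso - grid[lo]) / (grid[hi] - grid[lo])
    return nodes[lo], nodes[hi], float(frac)


def beta_fprime_param(
    table: ParameterTable,
    z: Union[int, str],
    s,
    b_iso: float,
) -> np.ndarray:
    """Parameterized beta*f'(s, B_iso) in Angstrom, clamped non-negative.

    Vectorized over *s*.  Exact node queries return that node's fitted
    curve; intermediate B_iso interpolates linearly between the two
    bracketing node curves evaluated at the exact s.
    """
    z = atomic_number(z)
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise ValueError("scattering parameter s must be >= 0")
    lo, hi, frac = _bracketing_nodes(table, z, float(b_iso))
    if frac == 0.0:
        value = lo.evaluate(s)
    else:
        value = (1.0 - frac) * lo.evaluate(s) + frac * hi.evaluate(s)
    return np.where(s > S_MAX, 0.0, np.maximum(value, 0.0))


def complex_scattering_factor(
    table: ParameterTable,
    z: Union[int, str],
    s,
    b_iso: float,
    voltage: float,
    born_table=None,
) -> ComplexScatteringFactor:
    """The relativistic complex scattering factor gamma*f + i*gamma*f'.

    Parameters
    ----------
    table : ParameterTable
        Fitted absorptive parameter table containing *z*.
    z : int or str
        Element (atomic number or symbol).
    s : array_like
        sin(theta)/lambda in 1/A.
    b_iso : float
        Isotropic Debye-Waller factor in A^2 (within the table range).
    voltage : float
        Accelerating voltage in volts; must be > 0 (beta = 0 at rest would
        make f' = beta f' / beta undefined).

    Examples
    --------
    >>> # table built earlier for carbon
    >>> fac = complex_scattering_factor(table, "C", 0.0, 0.5, 200e3)
    ... # doctest: +SKIP
    """
    beam = beam_parameters(voltage)
    if beam.beta == 0.0:
        raise ValueError("voltage must be > 0 for the absorptive part (beta = 0)")
    z = atomic_number(z)
    born = born_table if born_table is not None else default_born_table()
    real = beam.gamma * born.factor(z, s)
    imag = beam.gamma * beta_fprime_param(table, z, s, b_iso) / beam.beta
    return ComplexScatteringFactor(real=real, imag=imag)
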