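"""Complex absorptive structure factors for a P1 crystal model.

The structure factor of reflection g sums the complex scattering factors of
all atoms in the unit cell with their temperature factors and phases::

    F_g = sum_n  occ_n [gamma f_n(s) + i gamma f'_n(s)] exp(-B_n s^2)
                 exp(-2 pi i g . r_n),          s = |g| / 2

with s = sin(theta)/lambda from the reciprocal metric of the cell,
exp(-B s^2) the isotropic Debye-Waller temperature factor, and the phase
convention exp(-2 pi i h.x) fixed package-wide (only consistency matters
for |F|^2; the sign is documented here and pinned by tests).

Crystals are described by a minimal CIF subset (cell, P1 atom-site loop
with fractional coordinates, B_iso or U_iso, optional occupancy); CIF
syntax is handled by gemmi.  Space-group expansion is out of scope: sites
are taken literally (P1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .born import atomic_number, default_born_table, element_symbol
from .fast_eval import complex_scattering_factor
from .parameterization import ParameterTable

__all__ = [
    "AtomSite",
    "CrystalModel",
    "Reflection",
    "read_cif",
    "structure_factor",
    "reflection_list",
    "write_reflection_list",
    "U_TO_B",
]

#: B = 8 pi^2 U conversion between the mean-square displacement conventions
U_TO_B = 8.0 * math.pi**2


@dataclass(frozen=True)
class AtomSite:
    """One atom in the unit cell (fractional coordinates, P1)."""

    element: int  # atomic number
    frac_xyz: tuple[float, float, float]
    b_iso: float  # Angstrom^2
    occupancy: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.b_iso < 0:
            raise ValueError(f"site {self.label or self.element}: B_iso must be >= 0")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"site {self.label or self.element}: occupancy must be in [0, 1]")
        if not all(math.isfinite(x) for x in self.frac_xyz):
            raise ValueError(f"site {self.label or self.element}: non-finite coordinates")


@dataclass
class CrystalModel:
    """Unit cell (lengths in Angstrom, angles in degrees) plus explicit sites."""

    cell: tuple[float, float, float, float, float, float]
    sites: list[AtomSite] = field(default_factory=list)

    def __post_init__(self) -> None:
        import gemmi

        self._unit_cell = gemmi.UnitCell(*self.cell)
        if self._unit_cell.volume <= 0:
            raise ValueError(f"unit cell {self.cell} has non-positive volume")
        if not self.sites:
            raise ValueError("a crystal model needs at least one atom site")

    @property
    def volume(self) -> float:
        return self._unit_cell.volume

    def s_of_hkl(self, hkl: Sequence[int]) -> float:
        """s = sin(theta)/lambda = |g|/2 = 1/(2 d_hkl) from the cell metric."""
        h, k, l = (int(v) for v in hkl)
        if (h, k, l) == (0, 0, 0):
            return 0.0
        d = self._unit_cell.calculate_d((h, k, l))
        return 1.0 / (2.0 * d)


@dataclass(frozen=True)
class Reflection:
    """One reflection: integer hkl, |g| and s = |g|/2 in 1/A."""

    hkl: tuple[int, int, int]
    g_mag: float
    s: float


def _cif_value(block, tag: str) -> Optional[str]:
    value = block.find_value(tag)
    if value is None:
        return None
    return value


def _as_float(text: str) -> float:
    """Parse a CIF numeric value, dropping any '(esd)' suffix."""
    import gemmi

    return gemmi.cif.as_number(text)


def read_cif(path: Union[str, Path]) -> CrystalModel:
    """Parse the minimal CIF dialect into a :class:`CrystalModel`.

    Required tags: ``_cell_length_{a,b,c}``, ``_cell_angle_{alpha,beta,gamma}``
    and an ``_atom_site_*`` loop with fractional coordinates.  Displacement
    comes from ``_atom_site_B_iso_or_equiv`` or ``_atom_site_U_iso_or_equiv``
    (converted as B = 8 pi^2 U); occupancy defaults to 1.  Sites are taken
    as written (P1; no symmetry expansion).
    """
    import gemmi

    doc = gemmi.cif.read_file(str(path))
    block = doc.sole_block()

    cell_vals = []
    for tag in (
        "_cell_length_a", "_cell_length_b", "_cell_length_c",
        "_cell_angle_alpha", "_cell_angle_beta", "_cell_angle_gamma",
    ):
        raw = _cif_value(block, tag)
        if raw is None:
            raise ValueError(f"CIF {path}: missing required tag {tag}")
        cell_vals.append(_as_float(raw))

    xs = block.find_loop("_atom_site_fract_x")
    ys = block.find_loop("_atom_site_fract_y")
    zs = block.find_loop("_atom_site_fract_z")
    if len(xs) == 0:
        raise ValueError(f"CIF {path}: missing _atom_site_fract_x loop")
    n = len(xs)

    def loop_or_none(tag):
        col = block.find_loop(tag)
        return list(col) if len(col) == n else None

    labels = loop_or_none("_atom_site_label")
    symbols = loop_or_none("_atom_site_type_symbol")
    b_col = loop_or_none("_atom_site_B_iso_or_equiv")
    u_col = loop_or_none("_atom_site_U_iso_or_equiv")
    occ_col = loop_or_none("_atom_site_occupancy")
    if symbols is None and labels is None:
        raise ValueError(f"CIF {path}: need _atom_site_type_symbol or _atom_site_label")
    if b_col is None and u_col is None:
        raise ValueError(
            f"CIF {path}: need _atom_site_B_iso_or_equiv or _atom_site_U_iso_or_equiv"
        )

    sites = []
    for i in range(n):
        raw_symbol = (symbols[i] if symbols else labels[i]).strip()
        # strip trailing site-numbering/charge from e.g. "C1", "O2-"
        symbol = "".join(ch for ch in raw_symbol if ch.isalpha())[:2]
        try:
            z = atomic_number(symbol)
        except LookupError:
            try:
                z = atomic_number(symbol[:1])
            except LookupError:
                raise LookupError(
                    f"CIF {path}: unknown element symbol {raw_symbol!r} (site {i})"
                ) from None
        b_iso = _as_float(b_col[i]) if b_col else U_TO_B * _as_float(u_col[i])
        sites.append(
            AtomSite(
                element=z,
                frac_xyz=(_as_float(xs[i]), _as_float(ys[i]), _as_float(zs[i])),
                b_iso=b_iso,
                occupancy=_as_float(occ_col[i]) if occ_col else 1.0,
                label=labels[i] if labels else raw_symbol,
            )
        )
    return CrystalModel(cell=tuple(cell_vals), sites=sites)


def structure_factor(
    model: CrystalModel,
    hkl: Sequence[int],
    table: ParameterTable,
    voltage: float,
    born_table=None,
) -> complex:
    """Complex absorptive structure factor F_g in Angstrom for one reflection."""
    born = born_table if born_table is not None else default_born_table()
    h = np.asarray([int(v) for v in hkl])
    s = model.s_of_hkl(h)
    total = 0.0 + 0.0j
    for site in model.sites:
        try:
            factor = complex_scattering_factor(
                table, site.element, s, site.b_iso, voltage, born_table=born
            )
        except ValueError as err:
            raise ValueError(
                f"site {site.label or element_symbol(site.element)}: {err}"
            ) from err
        phase = np.exp(-2j * np.pi * float(h @ np.asarray(site.frac_xyz)))
        debye_waller = math.exp(-site.b_iso * s * s)
        total += site.occupancy * complex(factor.real + 1j * factor.imag) * debye_waller * phase
    return total


def reflection_list(
    model: CrystalModel,
    hkl_max: int,
    table: ParameterTable,
    voltage: float,
    born_table=None,
    s_max: Optional[float] = None,
) -> list[tuple[Reflection, complex]]:
    """All reflections with |h|,|k|,|l| <= hkl_max (000 excluded), with F_g."""
    out = []
    rng = range(-hkl_max, hkl_max + 1)
    for h in rng:
        for k in rng:
            for l in rng:
                if (h, k, l) == (0, 0, 0):
                    continue
                s = model.s_of_hkl((h, k, l))
                if s_max is not None and s > s_max:
                    continue
                F = structure_factor(model, (h, k, l), table, voltage, born_table)
                out.append((Reflection(hkl=(h, k, l), g_mag=2.0 * s, s=s), F))
    return out


def write_reflection_list(
    path: Union[str, Path],
    reflections: Sequence[tuple[Reflection, complex]],
) -> None:
    """Columnar text output: h k l s Re(F) Im(F) |F|^2."""
    lines = ["#  h   k   l        s        Re(F)        Im(F)       |F|^2"]
    for refl, F in reflections:
        h, k, l = refl.hkl
        lines.append(
            f"{h:4d}{k:4d}{l:4d} {refl.s:9.5f} {F.real:12.6f} {F.imag:12.6f} "
            f"{abs(F)**2:12.6f}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
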