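"""Analytic Born electron scattering factors f(s) for neutral, spherical atoms.

Two functional forms are supported behind one interface:

* a five-term Gaussian sum ``f(s) = sum_i a_i exp(-b_i s^2)`` with
  ``s = sin(theta)/lambda`` in inverse Angstrom -- the parameterization of
  Peng as tabulated in the International Tables for Crystallography
  (shipped with gemmi), which is the default backend; and
* the rational-Gaussian hybrid of Lobato & Van Dyck,
  ``f(g) = sum_i a_i (2 + b_i g^2) / (1 + b_i g^2)^2`` written in terms of
  ``g = 2 s``, for user-supplied coefficient files.

Every backend converts internally so that the public argument is always
``s = sin(theta)/lambda``; a factor-of-two slip between the s and g
conventions would silently corrupt every downstream absorptive factor, so
the convention travels with the coefficients and is pinned by tests on the
closed-form value at s = 0.

The default table covers Z = 1..103: Z <= 98 from gemmi, Z = 99..103 from
a synthetic extrapolation (see :mod:`edafs._synthetic_heavy`).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np

from ._synthetic_heavy import SYNTHETIC_HEAVY_COEFFICIENTS

__all__ = [
    "BornCoefficients",
    "GaussianBornTable",
    "LobatoBornTable",
    "GaussianAtom",
    "born_factor",
    "default_born_table",
    "element_symbol",
    "atomic_number",
    "MAX_Z",
    "DEFAULT_TABLE_SHA256",
]

MAX_Z = 103

# SHA-256 of the default table's canonical coefficient dump; guards against
# silent changes in the upstream gemmi table or the synthetic extension.
DEFAULT_TABLE_SHA256 = "d1fd681b4a00798b6f117cc0cdeecf0af7cfd207c267cf4d168087d5a3b155e5"


def element_symbol(z: int) -> str:
    import gemmi

    if not 1 <= int(z) <= MAX_Z:
        raise LookupError(f"no element with atomic number {z} (valid range 1..{MAX_Z})")
    return gemmi.Element(int(z)).name


def atomic_number(symbol_or_z: Union[int, str]) -> int:
    """Resolve an element symbol or atomic number to an atomic number."""
    import gemmi

    if isinstance(symbol_or_z, str) and not symbol_or_z.isdigit():
        el = gemmi.Element(symbol_or_z)
        z = el.atomic_number
        if z == 0:
            raise LookupError(f"unknown element symbol {symbol_or_z!r}")
    else:
        z = int(symbol_or_z)
    if not 1 <= z <= MAX_Z:
        raise LookupError(f"atomic number {z} outside the tabulated range 1..{MAX_Z}")
    return z


@dataclass(frozen=True)
class BornCoefficients:
    """Coefficients of one element's analytic Born factor.

    ``convention`` records the argument the coefficients were published in:
    ``"s"`` (sin theta / lambda) or ``"g"`` (= 2 s).  ``form`` is
    ``"gaussian"`` or ``"lobato"``.
    """

    atomic_number: int
    symbol: str
    a: tuple[float, ...]
    b: tuple[float, ...]
    convention: str = "s"
    form: str = "gaussian"
    source: str = ""

    def __post_init__(self) -> None:
        if len(self.a) != 5 or len(self.b) != 5:
            raise ValueError(
                f"expected exactly 5 (a_i, b_i) pairs for Z={self.atomic_number}, "
                f"got {len(self.a)} and {len(self.b)}"
            )
        if self.convention not in ("s", "g"):
            raise ValueError(f"unknown argument convention {self.convention!r}")

    def f_zero(self) -> float:
        """Closed-form f at zero scattering vector."""
        if self.form == "lobato":
            return 2.0 * float(np.sum(self.a))
        return float(np.sum(self.a))

    def evaluate(self, s) -> np.ndarray:
        """Evaluate f at s = sin(theta)/lambda (array-valued, Angstrom)."""
        s = np.asarray(s, dtype=float)
        if np.any(s < 0):
            raise ValueError("scattering parameter s must be >= 0")
        a = np.asarray(self.a)
        b = np.asarray(self.b)
        arg = 2.0 * s if self.convention == "g" else s
        x2 = arg[..., None] ** 2
        if self.form == "lobato":
            denom = 1.0 + b * x2
            terms = a * (2.0 + b * x2) / (denom * denom)
        else:
            terms = a * np.exp(-np.minimum(b * x2, 700.0))
        return terms.sum(axis=-1)


class GaussianBornTable:
    """Default Born-factor backend: Peng Gaussian sums for Z = 1..103.

    Coefficients for Z <= 98 are read from gemmi's copy of the International
    Tables parameterization at construction time; Z = 99..103 use the
    synthetic extension.
    """

    source = "Peng (International Tables 4.3.2.2, via gemmi) + synthetic Es-Lr"

    def __init__(self) -> None:
        import gemmi

        entries: dict[int, BornCoefficients] = {}
        for z in range(1, 99):
            coef = gemmi.Element(z).c4322
            entries[z] = BornCoefficients(
                atomic_number=z,
                symbol=gemmi.Element(z).name,
                a=tuple(coef.a),
                b=tuple(coef.b),
                convention="s",
                form="gaussian",
                source="Peng/IT 4.3.2.2 (gemmi)",
            )
        for z, (a, b) in SYNTHETIC_HEAVY_COEFFICIENTS.items():
            entries[z] = BornCoefficients(
                atomic_number=z,
                symbol=gemmi.Element(z).name,
                a=a,
                b=b,
                convention="s",
                form="gaussian",
                source="synthetic extrapolation (edafs._synthetic_heavy)",
            )
        self._entries = entries

    @property
    def elements(self) -> list[int]:
        return sorted(self._entries)

    def coefficients(self, z: int) -> BornCoefficients:
        z = int(z)
        if z not in self._entries:
            raise LookupError(
                f"no Born coefficients for atomic number {z} "
                f"(element {element_symbol(z) if 1 <= z <= MAX_Z else '?'})"
            )
        return self._entries[z]

    def factor(self, z: int, s) -> np.ndarray:
        """Born factor f(Z, s) in Angstrom, vectorized over s."""
        return self.coefficients(z).evaluate(s)

    def checksum(self) -> str:
        payload = json.dumps(
            {
                str(z): [list(np.round(c.a, 6)), list(np.round(c.b, 6))]
                for z, c in sorted(self._entries.items())
            },
            sort_keys=True,
        ).encode()
        return hashlib.sha256(payload).hexdigest()


class LobatoBornTable:
    """Born-factor backend for the Lobato-Van Dyck rational-Gaussian form.

    Coefficients are supplied by the user as a JSON file::

        {"source": "...", "convention": "g", "form": "lobato",
         "elements": [{"atomic_number": 6, "symbol": "C",
                       "a": [...5...], "b": [...5...]}, ...]}
    """

    def __init__(self, path: Union[str, Path]) -> None:
        raw = json.loads(Path(path).read_text())
        self.source = raw.get("source", str(path))
        convention = raw.get("convention", "g")
        form = raw.get("form", "lobato")
        self._entries = {}
        for rec in raw["elements"]:
            z = int(rec["atomic_number"])
            self._entries[z] = BornCoefficients(
                atomic_number=z,
                symbol=rec.get("symbol", element_symbol(z)),
                a=tuple(float(v) for v in rec["a"]),
                b=tuple(float(v) for v in rec["b"]),
                convention=convention,
                form=form,
                source=self.source,
            )

    @property
    def elements(self) -> list[int]:
        return sorted(self._entries)

    def coefficients(self, z: int) -> BornCoefficients:
        z = int(z)
        if z not in self._entries:
            raise LookupError(f"no Born coefficients for atomic number {z} in {self.source}")
        return self._entries[z]

    def factor(self, z: int, s) -> np.ndarray:
        return self.coefficients(z).evaluate(s)


@dataclass(frozen=True)
class GaussianAtom:
    """Single-Gaussian mock atom ``f(s) = amplitude * exp(-width * s^2)``.

    Its two-beam absorptive integral has a closed form (see
    :func:`edafs.integral.gaussian_atom_closed_form`), which makes it the
    independent oracle for the numerical quadrature and for validation-map
    plumbing tests.
    """

    amplitude: float = 3.0
    width: float = 1.5  # Angstrom^2

    def factor(self, s) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        return self.amplitude * np.exp(-self.width * s * s)


_default_table: GaussianBornTable | None = None


def default_born_table() -> GaussianBornTable:
    """Singleton default backend (built lazily from gemmi)."""
    global _default_table
    if _default_table is None:
        _default_table = GaussianBornTable()
    return _default_table


def born_factor(z: Union[int, str], s, table=None) -> np.ndarray:
    """Born electron scattering factor f(Z, s) in Angstrom.

    Parameters
    ----------
    z : int or str
        Atomic number 1..103 or element symbol.
    s : array_like
        Scattering parameter sin(theta)/lambda in inverse Angstrom, >= 0.
    table : optional
        Alternative backend (anything with a ``factor(z, s)`` method).
    """
    table = table if table is not None else default_born_table()
    return table.factor(atomic_number(z), s)
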