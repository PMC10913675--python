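"""SYNTHETIC stand-in Born-factor coefficients for Es-Lr (Z = 99-103).

The Gaussian electron scattering-factor table shipped with gemmi (the
International Tables parameterization of Peng) stops at californium
(Z = 98).  To cover the five remaining actinides the coefficients below
were CONSTRUCTED, not measured: the scattering-factor curves f(s; Z) for
Z = 92-98 were extrapolated pointwise in Z with a quadratic polynomial on
a dense s grid (0-12 inverse Angstrom) and the extrapolated curve was then
refit with a bounded 5-Gaussian sum.  ``generate_synthetic_coefficients``
reproduces the table from scratch.

These are smooth, positive, monotonically decreasing stand-ins with the
right magnitude and Z trend; they are NOT a published parameterization and
should be replaced by one (e.g. via a user-supplied coefficient file) for
quantitative work on Z >= 99.
"""

from __future__ import annotations

import numpy as np

__all__ = ["SYNTHETIC_HEAVY_COEFFICIENTS", "generate_synthetic_coefficients"]

# Z -> (a1..a5 in Angstrom, b1..b5 in Angstrom^2); f(s) = sum a_i exp(-b_i s^2)
SYNTHETIC_HEAVY_COEFFICIENTS: dict[int, tuple[tuple[float, ...], tuple[float, ...]]] = {
    99: (
        (1.185422, 2.742442, 4.294099, 3.476639, 5.125790),
        (0.235101, 1.694854, 6.612303, 20.887053, 64.267028),
    ),
    100: (
        (1.152431, 2.632627, 3.200457, 3.128737, 6.555762),
        (0.226663, 1.601572, 5.619909, 12.410226, 48.395892),
    ),
    101: (
        (1.133662, 0.000000, 2.815835, 5.042115, 7.600619),
        (0.220230, 0.373554, 1.603866, 7.079957, 39.000848),
    ),
    102: (
        (1.070918, 2.523285, 4.716652, 8.286030, 0.000000),
        (0.208097, 1.420362, 5.943168, 33.334226, 89.161263),
    ),
    103: (
        (1.014072, 2.254012, 4.411234, 0.000000, 9.000321),
        (0.197489, 1.261895, 5.006321, 24.741836, 29.154767),
    ),
}


def generate_synthetic_coefficients(atomic_number: int):
    """Re-derive the synthetic coefficients for one element from gemmi's table.

    Returns ``(a, b)`` arrays of length 5.  Used by the test suite to guard
    the frozen literals above against silent edits (and against drift in the
    underlying gemmi table).
    """
    import gemmi
    from scipy.optimize import least_squares

    if atomic_number not in range(99, 104):
        raise ValueError(f"synthetic extension only covers Z=99..103, got {atomic_number}")

    s_grid = np.concatenate([np.linspace(0.0, 2.0, 81), np.linspace(2.05, 12.0, 100)])
    base_z = np.arange(92, 99)

    def peng_curve(z):
        c = gemmi.Element(int(z)).c4322
        a, b = np.asarray(c.a), np.asarray(c.b)
        return (a[None, :] * np.exp(-b[None, :] * s_grid[:, None] ** 2)).sum(1)

    curves = np.array([peng_curve(z) for z in base_z])
    target = np.array(
        [np.polyval(np.polyfit(base_z, curves[:, j], 2), atomic_number)
         for j in range(len(s_grid))]
    )
    b0 = np.geomspace(0.2, 120.0, 5)
    design = np.exp(-b0[None, :] * s_grid[:, None] ** 2)
    a0 = np.clip(np.linalg.lstsq(design, target, rcond=None)[0], 1e-6, None)
    lo = np.concatenate([np.zeros(5), np.full(5, 1e-3)])
    hi = np.concatenate([np.full(5, 50.0), np.full(5, 1e4)])

    def resid(x):
        return (x[None, :5] * np.exp(-x[None, 5:] * s_grid[:, None] ** 2)).sum(1) - target

    fit = least_squares(
        resid, np.clip(np.concatenate([a0, b0]), lo, hi), bounds=(lo, hi),
        method="trf", xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=20000,
    )
    order = np.argsort(fit.x[5:])
    return fit.x[:5][order], fit.x[5:][order]
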