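"""Compact Gaussian-sum parameterization of the absorptive factor.

For each element, beta*f'(s) at a fixed Debye-Waller node B_iso is
approximated by four Gaussians plus a constant::

    beta f'(s) ~ a1 exp(-b1 s^2) + ... + a4 exp(-b4 s^2) + c

i.e. nine numbers per (element, B_iso) node.  Thirteen B_iso nodes spanning
0.1-4 A^2 give 9 x 13 = 117 numbers per element; intermediate B_iso values
are obtained downstream by linear interpolation between the two bracketing
node curves (:mod:`edafs.fast_eval`).

Fitting strategy
----------------
The fit target is the clamped direct integral sampled on 100 uniform points
in s over [0, 6] 1/A.  The quality gate is *relative*: the fitted curve must
stay within 0.1% of the direct value wherever the direct value exceeds
10^-3 of its maximum (below that floor relative error is meaningless -- the
curve is passing through zero -- and the error is suppressed in use by the
temperature factor exp(-B s^2)).

Least squares is solved with a trust-region-reflective algorithm via a
variable-projection split: the model is linear in the four amplitudes and
the constant, so the outer optimization runs over the four (log) widths
only, with the amplitudes solved exactly at each step; a full 9-parameter
polish with an analytic Jacobian follows.  Amplitudes are left free in
sign: tracking three decades of relative accuracy next to the clamped zero
region requires a slowly varying negative component cancelling against the
constant, and an all-positive sum cannot reach the 0.1% gate.  Points below
the relative floor enter the objective with a small "soft" weight that is
relaxed in stages (2e-2, 2e-3, 2e-4, 0) until the gate passes, which keeps
the model tail beyond the zero crossing as small as the gate allows.

All initialization is deterministic, so identical configurations produce
byte-identical tables.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from scipy.optimize import least_squares

from .born import default_born_table, element_symbol
from .integral import IntegrationError, QuadratureConfig, absorptive_integral

__all__ = [
    "DEFAULT_B_GRID",
    "DEFAULT_S_GRID",
    "FORMAT_VERSION",
    "GaussianSumParams",
    "ParameterTable",
    "FitError",
    "sample_curve",
    "fit_node",
    "build_table",
]

#: The 13 Debye-Waller nodes (A^2).  Denser at low B_iso, where the surface
#: beta*f'(s, B) is most strongly curved and linear interpolation between
#: nodes is least reliable.
DEFAULT_B_GRID: tuple[float, ...] = (
    0.1, 0.2, 0.3, 0.5, 0.7, 1.0, 1.4, 1.8, 2.2, 2.6, 3.0, 3.5, 4.0,
)

#: 100 uniform s values on [0, 6] 1/A used to sample the direct integral.
DEFAULT_S_GRID: np.ndarray = np.linspace(0.0, 6.0, 100)

FORMAT_VERSION = "1.0"

_RESIDUAL_GATE = 1e-3  # max relative deviation allowed at gated points
_RELATIVE_FLOOR = 1e-3  # gate applies where y >= floor * max(y)
_WIDTH_BOUNDS = (1e-4, 1e3)  # Angstrom^2
_SOFT_WEIGHT_LADDER = (2e-2, 2e-3, 2e-4, 0.0)
_EXP_CLIP = 500.0


class FitError(RuntimeError):
    """Raised when a node fit cannot reach the residual gate.

    Carries the per-point relative residual profile of the best attempt.
    """

    def __init__(self, message: str, residual_profile: np.ndarray):
        super().__init__(message)
        self.residual_profile = residual_profile


@dataclass(frozen=True)
class GaussianSumParams:
    """Fitted 9-parameter model for one (element, B_iso node).

    ``evaluate`` returns the raw model; negative values are clamped only at
    the point of use.
    """

    atomic_number: int
    b_iso: float
    a: tuple[float, float, float, float]
    b: tuple[float, float, float, float]
    c: float
    max_rel_residual: float = float("nan")
    #: soft weight applied to sub-floor points by the accepted fit stage
    #: (diagnostic; smaller means the zero-region tail is less controlled)
    soft_weight: float = float("nan")

    def __post_init__(self) -> None:
        if len(self.a) != 4 or len(self.b) != 4:
            raise ValueError("exactly 4 (a_i, b_i) pairs are required")
        if any(bi <= 0 for bi in self.b):
            raise ValueError("all width parameters b_i must be > 0")

    def evaluate(self, s) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        a = np.asarray(self.a)
        b = np.asarray(self.b)
        return (
            a * np.exp(-np.minimum(b * s[..., None] ** 2, _EXP_CLIP))
        ).sum(axis=-1) + self.c

    def as_dict(self) -> dict:
        return {
            "b_iso": self.b_iso,
            "a": list(self.a),
            "b": list(self.b),
            "c": self.c,
            "max_rel_residual": self.max_rel_residual,
            "soft_weight": self.soft_weight,
        }


def sample_curve(
    atomic_number: int,
    b_iso: float,
    s_grid: Optional[np.ndarray] = None,
    config: Optional[QuadratureConfig] = None,
    born_table=None,
) -> np.ndarray:
    """Clamped direct-integral values of beta*f' on a grid of s.

    Integration failures are re-raised annotated with (Z, B_iso, s).
    """
    table = born_table if born_table is not None else default_born_table()
    coef = table.coefficients(atomic_number)
    s_grid = DEFAULT_S_GRID if s_grid is None else np.asarray(s_grid, dtype=float)
    out = np.empty_like(s_grid)
    for i, s in enumerate(s_grid):
        try:
            out[i] = max(absorptive_integral(coef.evaluate, float(s), b_iso, config), 0.0)
        except IntegrationError as err:
            raise IntegrationError(
                f"sampling failed for Z={atomic_number}, B_iso={b_iso}, s={s}: {err}",
                estimates=err.estimates,
            ) from err
    return out


# ----------------------------------------------------------------- fitting


def _model(a: np.ndarray, b: np.ndarray, c: float, s: np.ndarray) -> np.ndarray:
    return (a[None, :] * np.exp(-np.minimum(b[None, :] * s[:, None] ** 2, _EXP_CLIP))).sum(1) + c


def _solve_linear(log_b: np.ndarray, s: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Optimal amplitudes and constant for fixed widths (weighted lstsq)."""
    b = np.exp(log_b)
    design = np.column_stack(
        [np.exp(-np.minimum(bb * s**2, _EXP_CLIP)) for bb in b] + [np.ones_like(s)]
    )
    coef, *_ = np.linalg.lstsq(design * w[:, None], y * w, rcond=None)
    residual = (design @ coef - y) * w
    return coef, residual


def _fit_varpro(s, y, w, b0) -> tuple[np.ndarray, np.ndarray, float]:
    log_bounds = (np.log(_WIDTH_BOUNDS[0]), np.log(_WIDTH_BOUNDS[1]))

    def resid(log_b):
        return _solve_linear(log_b, s, y, w)[1]

    fit = least_squares(
        resid, np.log(b0), bounds=log_bounds, method="trf",
        xtol=1e-10, ftol=1e-10, gtol=1e-10, max_nfev=120,
    )
    coef, _ = _solve_linear(fit.x, s, y, w)
    return coef[:4], np.exp(fit.x), float(coef[4])


def _polish(s, y, w, a, b, c, deep: bool = False) -> tuple[np.ndarray, np.ndarray, float]:
    """Joint 9-parameter refinement with an analytic Jacobian.

    The quick variant is used while scanning starts; the *deep* variant
    (tighter tolerances, more iterations) refines the accepted candidate.
    """
    tol = 1e-15 if deep else 5e-12
    nfev = 400 if deep else 80
    x0 = np.concatenate([a, np.log(b), [c]])

    def resid(x):
        return (_model(x[:4], np.exp(x[4:8]), x[8], s) - y) * w

    def jac(x):
        widths = np.exp(x[4:8])
        basis = np.exp(-np.minimum(widths[None, :] * s[:, None] ** 2, _EXP_CLIP))
        out = np.empty((len(s), 9))
        out[:, :4] = basis
        # d/d(log b) = -a * (b s^2) * exp(-b s^2)
        out[:, 4:8] = -x[None, :4] * basis * (widths[None, :] * s[:, None] ** 2)
        out[:, 8] = 1.0
        return out * w[:, None]

    lo = np.concatenate([np.full(4, -np.inf), np.full(4, np.log(_WIDTH_BOUNDS[0])), [-np.inf]])
    hi = np.concatenate([np.full(4, np.inf), np.full(4, np.log(_WIDTH_BOUNDS[1])), [np.inf]])
    fit = least_squares(
        resid, np.clip(x0, lo, hi), jac=jac, bounds=(lo, hi), method="trf",
        xtol=tol, ftol=tol, gtol=tol, max_nfev=nfev,
    )
    return fit.x[:4], np.exp(fit.x[4:8]), float(fit.x[8])


def _lawson(s, y, mask, w0, a, b, c, iters: int = 24):
    """Iteratively reweighted refinement toward the discrete minimax.

    Plain weighted least squares minimizes the *sum* of squared relative
    errors; the residual gate is on the *maximum*.  Lawson's algorithm
    closes most of the gap by repeatedly up-weighting the points carrying
    the largest residual.  Only gated points are reweighted, so whatever
    soft tail control the accepted stage had is preserved.
    """
    lw = np.ones_like(y)
    best = None
    for it in range(iters):
        a, b, c = _polish(s, y, w0 * np.sqrt(lw), a, b, c, deep=(it % 5 == 4))
        mr, profile = _gated_residual(s, y, mask, a, b, c)
        if best is None or mr < best[0]:
            best = (mr, (a, b, c), profile)
        r = np.where(mask, profile, 0.0)
        lw = lw * np.maximum(r / max(mr, 1e-300), 1e-4)
        gated_mean = lw[mask].mean()
        if gated_mean > 0:
            lw[mask] /= gated_mean
        lw[~mask] = 1.0
    return best


def _minimax_rescue(s, y, mask, a, b, c, mr0):
    """Exact discrete minimax on the gated points (SLSQP), as a last resort."""
    from scipy.optimize import minimize

    sm, ym = s[mask], y[mask]
    x0 = np.concatenate([a, np.log(b), [c, mr0]])
    log_lo, log_hi = np.log(_WIDTH_BOUNDS[0]), np.log(_WIDTH_BOUNDS[1])
    bounds = [(None, None)] * 4 + [(log_lo, log_hi)] * 4 + [(None, None), (0.0, None)]

    def cons(x):
        r = (_model(x[:4], np.exp(x[4:8]), x[8], sm) - ym) / ym
        return np.concatenate([x[9] - r, x[9] + r])

    res = minimize(
        lambda x: x[9], x0, method="SLSQP", bounds=bounds,
        constraints=[{"type": "ineq", "fun": cons}],
        options={"maxiter": 300, "ftol": 1e-14},
    )
    a2, b2, c2 = res.x[:4], np.exp(res.x[4:8]), float(res.x[8])
    mr, profile = _gated_residual(s, y, mask, a2, b2, c2)
    return mr, (a2, b2, c2), profile


def _gated_residual(s, y, mask, a, b, c) -> tuple[float, np.ndarray]:
    model = _model(a, b, c, s)
    profile = np.zeros_like(y)
    profile[mask] = np.abs(model[mask] - y[mask]) / y[mask]
    return float(profile[mask].max()) if mask.any() else 0.0, profile


def _fit_curve(
    s: np.ndarray,
    y: np.ndarray,
    gate: float = _RESIDUAL_GATE,
    warm_init: Optional[tuple[np.ndarray, np.ndarray, float]] = None,
    ladder_start: Optional[float] = None,
) -> tuple[np.ndarray, np.ndarray, float, float, np.ndarray, float]:
    """Fit the 9-parameter model to one clamped curve.

    Returns (a, b, c, max_rel_residual, residual_profile, soft_weight);
    raises FitError if no weighting stage reaches the gate.  *warm_init*
    seeds the search (e.g. with the solution of a neighbouring B_iso node)
    and *ladder_start* truncates the soft-weight ladder to stages at or
    below a neighbour's accepted stage, since the binding stage varies
    slowly along the B_iso grid.
    """
    ymax = float(y.max())
    if ymax <= 0.0:
        # all-zero target (e.g. the B_iso = 0 limit): exact representation
        widths = np.geomspace(0.1, 100.0, 4)
        return np.zeros(4), widths, 0.0, 0.0, np.zeros_like(y), _SOFT_WEIGHT_LADDER[0]
    floor = _RELATIVE_FLOOR * ymax
    mask = y >= floor
    support = max(float(s[mask].max()), 0.3)
    spans = ((0.5, 50.0), (0.1, 200.0), (1.0, 20.0))
    best: tuple[float, tuple, np.ndarray, float] | None = None
    warm = warm_init
    ladder = tuple(
        a for a in _SOFT_WEIGHT_LADDER if ladder_start is None or a <= ladder_start
    ) or _SOFT_WEIGHT_LADDER
    for alpha in ladder:
        w = np.where(mask, 1.0 / np.maximum(y, floor), alpha / floor)
        stage_best: tuple[float, tuple, np.ndarray, float] | None = None
        starts: list = []
        if warm is not None:
            starts.append(("warm", warm))
        starts.extend(("span", sp) for sp in spans)
        for kind, item in starts:
            if kind == "warm":
                a, b, c = _polish(s, y, w, *item)
            else:
                lo, hi = item
                b0 = np.clip(
                    np.geomspace(lo / support**2, hi / support**2, 4),
                    1.2 * _WIDTH_BOUNDS[0],
                    0.9 * _WIDTH_BOUNDS[1],
                )
                a, b, c = _fit_varpro(s, y, w, b0)
                a, b, c = _polish(s, y, w, a, b, c)
            mr, profile = _gated_residual(s, y, mask, a, b, c)
            if stage_best is None or mr < stage_best[0]:
                stage_best = (mr, (a, b, c), profile, alpha)
            if mr <= 0.7 * gate:
                break
            if kind == "span" and stage_best[0] > 10.0 * gate:
                # the soft weight, not the width start, is the binding
                # constraint at this stage; drop to the next ladder rung
                break
        warm = stage_best[1]
        if best is None or stage_best[0] < best[0]:
            best = stage_best
        if stage_best[0] <= 0.9 * gate:
            # accept the largest soft weight (best tail control) that
            # passes with some margin
            best = stage_best
            break
    # deep-polish the accepted candidate under its own stage weights
    mr, (a, b, c), profile, alpha = best
    w = np.where(mask, 1.0 / np.maximum(y, floor), alpha / floor)
    a2, b2, c2 = _polish(s, y, w, a, b, c, deep=True)
    mr2, profile2 = _gated_residual(s, y, mask, a2, b2, c2)
    if mr2 <= mr:
        a, b, c, mr, profile = a2, b2, c2, mr2, profile2
    if mr > 0.85 * gate:
        # least squares minimizes the sum, the gate caps the max: refine
        # toward the minimax when the margin is thin
        refined = _lawson(s, y, mask, w, np.asarray(a), np.asarray(b), c)
        if refined[0] < mr:
            mr, (a, b, c), profile = refined
    if mr > gate:
        rescued = _minimax_rescue(s, y, mask, np.asarray(a), np.asarray(b), c, mr)
        if rescued[0] < mr:
            mr, (a, b, c), profile = rescued
    if mr > gate:
        raise FitError(
            f"node fit failed the {gate:.1%} residual gate (best {mr:.3e})",
            residual_profile=profile,
        )
    order = np.argsort(b)
    return a[order], b[order], c, mr, profile, alpha


def fit_node(
    atomic_number: int,
    b_iso: float,
    s_grid: Optional[np.ndarray] = None,
    config: Optional[QuadratureConfig] = None,
    born_table=None,
    curve: Optional[np.ndarray] = None,
    warm_start: Optional[GaussianSumParams] = None,
) -> GaussianSumParams:
    """Sample the direct integral at one B_iso node and fit the 9-parameter model.

    A pre-sampled *curve* may be passed to skip the integration step, and a
    neighbouring node's fit may be passed as *warm_start*.

    Raises
    ------
    FitError
        If the fitted curve misses the 0.1% relative gate; the error carries
        the residual profile (never silently accepted).
    """
    s_grid = DEFAULT_S_GRID if s_grid is None else np.asarray(s_grid, dtype=float)
    if curve is None:
        curve = sample_curve(atomic_number, b_iso, s_grid, config, born_table)
    y = np.asarray(curve, dtype=float)
    non_degenerate = int(np.sum(y > 0))
    if 0 < non_degenerate < 9:
        raise FitError(
            f"only {non_degenerate} non-degenerate points for Z={atomic_number}, "
            f"B_iso={b_iso}; need at least 9",
            residual_profile=np.zeros_like(y),
        )
    warm = None
    ladder_start = None
    if warm_start is not None and any(warm_start.a):
        warm = (np.asarray(warm_start.a), np.asarray(warm_start.b), warm_start.c)
        if math.isfinite(warm_start.soft_weight):
            ladder_start = warm_start.soft_weight
    try:
        a, b, c, mr, _, alpha = _fit_curve(s_grid, y, warm_init=warm, ladder_start=ladder_start)
    except FitError as err:
        raise FitError(
            f"Z={atomic_number} ({element_symbol(atomic_number)}), B_iso={b_iso}: {err}",
            residual_profile=err.residual_profile,
        ) from err
    return GaussianSumParams(
        atomic_number=int(atomic_number),
        b_iso=float(b_iso),
        a=tuple(float(v) for v in a),
        b=tuple(float(v) for v in b),
        c=float(c),
        max_rel_residual=mr,
        soft_weight=float(alpha),
    )


# ------------------------------------------------------------------ tables


@dataclass
class ParameterTable:
    """All fitted nodes for a set of elements, plus provenance metadata.

    ``failures`` records elements whose build aborted (message per Z); a
    table with failures is flagged incomplete but still usable for the
    elements it does contain.
    """

    b_iso_grid: tuple[float, ...]
    entries: dict[int, list[GaussianSumParams]] = field(default_factory=dict)
    failures: dict[int, str] = field(default_factory=dict)
    born_source: str = ""
    quadrature_hash: str = ""
    s_grid_spec: dict = field(default_factory=lambda: {"n": 100, "s_max": 6.0})

    @property
    def elements(self) -> list[int]:
        return sorted(self.entries)

    @property
    def complete(self) -> bool:
        return not self.failures

    @property
    def b_min(self) -> float:
        return self.b_iso_grid[0]

    @property
    def b_max(self) -> float:
        return self.b_iso_grid[-1]

    def nodes(self, atomic_number: int) -> list[GaussianSumParams]:
        z = int(atomic_number)
        if z not in self.entries:
            raise LookupError(
                f"element Z={z} not present in this parameter table "
                f"(covers {len(self.entries)} elements)"
            )
        return self.entries[z]

    def n_parameters(self, atomic_number: int) -> int:
        return 9 * len(self.nodes(atomic_number))

    def max_residual(self) -> float:
        return max(
            (node.max_rel_residual for nodes in self.entries.values() for node in nodes),
            default=0.0,
        )

    # -- serialization ----------------------------------------------------

    def to_json(self) -> str:
        doc = {
            "format_version": FORMAT_VERSION,
            "b_iso_grid": list(self.b_iso_grid),
            "born_source": self.born_source,
            "quadrature_hash": self.quadrature_hash,
            "s_grid": self.s_grid_spec,
            "elements": [
                {
                    "atomic_number": z,
                    "symbol": element_symbol(z),
                    "nodes": [node.as_dict() for node in self.entries[z]],
                }
                for z in self.elements
            ],
            "failures": {str(z): msg for z, msg in sorted(self.failures.items())},
        }
        return json.dumps(doc, indent=1, sort_keys=True)

    def save(self, path: Union[str, Path]) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: Union[str, Path]) -> "ParameterTable":
        doc = json.loads(Path(path).read_text())
        version = str(doc.get("format_version", "?"))
        if version.split(".")[0] != FORMAT_VERSION.split(".")[0]:
            raise ValueError(
                f"unsupported parameter-table format version {version!r} "
                f"(this reader understands major version {FORMAT_VERSION.split('.')[0]})"
            )
        table = cls(
            b_iso_grid=tuple(doc["b_iso_grid"]),
            born_source=doc.get("born_source", ""),
            quadrature_hash=doc.get("quadrature_hash", ""),
            s_grid_spec=doc.get("s_grid", {}),
        )
        for rec in doc["elements"]:
            z = int(rec["atomic_number"])
            table.entries[z] = [
                GaussianSumParams(
                    atomic_number=z,
                    b_iso=float(node["b_iso"]),
                    a=tuple(node["a"]),
                    b=tuple(node["b"]),
                    c=float(node["c"]),
                    max_rel_residual=float(node["max_rel_residual"]),
                    soft_weight=float(node.get("soft_weight", float("nan"))),
                )
                for node in rec["nodes"]
            ]
        table.failures = {int(z): msg for z, msg in doc.get("failures", {}).items()}
        return table


def build_table(
    elements: Sequence[int],
    b_iso_grid: Sequence[float] = DEFAULT_B_GRID,
    config: Optional[QuadratureConfig] = None,
    born_table=None,
    s_grid: Optional[np.ndarray] = None,
    checkpoint_dir: Optional[Union[str, Path]] = None,
    progress: bool = False,
) -> ParameterTable:
    """Fit the full parameter table for the requested elements.

    Deterministic given the configuration (fixed initialization, no
    randomness).  A node failure aborts that element; the element is
    recorded in ``table.failures`` and the build continues.  With
    *checkpoint_dir*, finished elements are written to disk and reused by a
    later call with the same quadrature configuration.
    """
    table = born_table if born_table is not None else default_born_table()
    config = config or QuadratureConfig()
    s_grid = DEFAULT_S_GRID if s_grid is None else np.asarray(s_grid, dtype=float)
    grid = tuple(float(b) for b in b_iso_grid)
    if list(grid) != sorted(grid):
        raise ValueError("b_iso_grid must be ascending")
    result = ParameterTable(
        b_iso_grid=grid,
        born_source=getattr(table, "source", repr(table)),
        quadrature_hash=config.config_hash(),
        s_grid_spec={"n": int(len(s_grid)), "s_max": float(s_grid[-1])},
    )
    ckpt = Path(checkpoint_dir) if checkpoint_dir else None
    if ckpt:
        ckpt.mkdir(parents=True, exist_ok=True)
    for z in sorted(int(z) for z in elements):
        if ckpt:
            cached = ckpt / f"element_{z:03d}_{config.config_hash()}.json"
            if cached.exists():
                partial = ParameterTable.load(cached)
                if partial.b_iso_grid == grid and z in partial.entries:
                    result.entries[z] = partial.entries[z]
                    continue
        try:
            # high-B nodes are the easiest fits; build them first so each
            # node seeds its lower-B neighbour (warm start + ladder stage)
            nodes: list[GaussianSumParams] = []
            for b in reversed(grid):
                nodes.append(
                    fit_node(
                        z, b, s_grid=s_grid, config=config, born_table=table,
                        warm_start=nodes[-1] if nodes else None,
                    )
                )
            nodes.reverse()
        except (FitError, IntegrationError) as err:
            result.failures[z] = str(err)
            if progress:
                print(f"  Z={z:3d} FAILED: {err}")
            continue
        result.entries[z] = nodes
        if progress:
            worst = max(node.max_rel_residual for node in nodes)
            print(f"  Z={z:3d} {element_symbol(z):2s} worst residual {worst:.2e}")
        if ckpt:
            single = ParameterTable(
                b_iso_grid=grid,
                entries={z: nodes},
                born_source=result.born_source,
                quadrature_hash=result.quadrature_hash,
                s_grid_spec=result.s_grid_spec,
            )
            single.save(ckpt / f"element_{z:03d}_{config.config_hash()}.json")
    return result
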