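# Methods

## Physical model

`edafs` models thermal diffuse scattering (TDS) as absorption: electrons
scattered by phonons leave the Bragg beams and are treated as lost to a
diffuse background.  Atoms vibrate independently and isotropically with
harmonic displacements (the Einstein model), with amplitude set by the
isotropic Debye–Waller factor `B_iso = 8 pi^2 <u^2>` in Å².  For a beam in
a two-beam condition, the loss appears as an imaginary part `f'` added to
the Born electron scattering factor, used as `gamma f + i gamma f'`
together with the temperature factor `exp(-B s^2)`, `s = sin(theta)/lambda
= g/2`.

### The absorptive integral

The package evaluates the voltage-independent product (all lengths in Å,
scattering arguments in Å⁻¹):

    beta f'(s, B) = (2 h / m0 c) ∬ f(u+) f(u-)
                    [ e^(−B s²) − e^(−B s²/2 − 2 B t²) ] dx dy

    u± = sqrt((s/2 ± x)² + y²),    t² = x² + y²

The integration plane is centred halfway between the incident and
diffracted beam directions, which makes the integrand even in both x and y;
integration runs over one quadrant and is multiplied by four.  The
prefactor is fixed by the optical theorem: at s = 0 the expression reduces
to `sigma_TDS / (2 lambda)` with `sigma_TDS = lambda² ∬ |f|² (1 − e^(−2M))`
the diffuse cross-section, and with the relativistic mass folded into the
`gamma` applied at evaluation time, the leftover factor is `h/(2 m0 c)` in
the unsymmetrized variables (equivalently `2h/m0 c` in the symmetric ones).
`h`, `m0`, `c`, `e` are CODATA 2018 values hard-coded at full precision.

Consequences built into the model and verified by the test suite:

* `B_iso = 0` gives exactly zero (no vibration, no diffuse loss); the code
  returns 0 without integrating.
* The bracket is negative wherever `2t² < s²/2`, so the raw integral turns
  negative at large `s` — formally amplification, physically spurious —
  and is clamped to zero everywhere downstream.  At `B_iso = 4 Å²` the
  clamped factor vanishes for all `s ≥ 2 Å⁻¹` (for C, Ga and Pb it is
  already gone near `s ≈ 1`).
* `beta f'(0, B)` grows with both `B_iso` and atomic number; the ratio
  `f/f'` at 200 kV is ≈ 13 for Pb and ≈ 160 for C.

### Quadrature

Tensor-product Gauss–Legendre on a truncated quadrant with a panel split
along x at the ridge `x = s/2` of the `f(u+)f(u-)` product.  The default
(`QuadratureConfig()`) starts at 48 nodes per panel per dimension and
doubles until two estimates agree to `rtol = 1e-7` (absolute floor
`1e-12 Å` where the value crosses zero), raising `IntegrationError` with
the last two estimates after 4 failed doublings.  The infinite domain is
cut at `max(6, s+6) * min(2, max(1, 1/sqrt(B)))` Å⁻¹; the `1/sqrt(B)`
stretch keeps the slowly-decaying bracket inside the window at small
`B_iso`.  `SURVEY_CONFIG` is a single fixed 48-node level with no
refinement (measured ~3e-4 worst-case relative error on gated curve
points, usually far better); it is the bulk-build preset.

A Gaussian model atom `f = A e^(−a u²)` makes every term of the integrand
an elementary 2-D Gaussian with the closed form

    beta f' = (2h/m0c) A² (π/2) e^(−a s²/2) [ e^(−B s²)/a − e^(−B s²/2)/(a+B) ]

which pins the integrand, the truncation, the symmetry factor and the
physical prefactor in one independent oracle (agreement ~1e-13; the test
gate is 1e-6).  A second oracle integrates the full plane without the
symmetry shortcut (agreement gated at 1e-8).

## Born factors

The default backend is the 5-term Gaussian electron scattering
parameterization tabulated in gemmi (`f(s) = Σ a_i e^(−b_i s²)`,
International Tables / Peng), covering Z = 1–98.  Es–Lr (Z = 99–103) have
no offline coefficient source; they are covered by a synthetic stand-in
(`_synthetic_heavy.py`): the f(s; Z) curves for Z = 92–98 are extrapolated
pointwise in Z with a quadratic and refit with a bounded 5-Gaussian.  The
stand-ins are smooth, positive, monotonically decreasing and follow the Z
trend, but are not a published parameterization; quantitative work on
Z ≥ 99 should supply proper coefficients through the pluggable backend.
The Lobato–Van Dyck rational-Gaussian form
`f(g) = Σ a_i (2 + b_i g²)/(1 + b_i g²)²` is implemented for user-supplied
JSON coefficient files; its `g = 2s` argument convention is stored with the
coefficients and converted internally, so the public API is uniformly in s
(a silent factor-of-two here would corrupt every downstream number, so the
convention is pinned by a closed-form test at s = 0).  A SHA-256 checksum
of the assembled default table guards against upstream drift.

Gaussian parameterizations decay faster than the true ~1/s² Rutherford
tail beyond their fitted range; under the `exp(−2Bs'²)` bracket and the
`f·f` product this has negligible effect on the integral at the B_iso
values tabulated here, but it is the main physical difference from a
rational-form backend.

## The 9-parameter compression

Per element and per `B_iso` node, the clamped direct integral sampled on
100 uniform points in `s ∈ [0, 6] Å⁻¹` is fit by four Gaussians plus a
constant.  The node grid is

    0.1 0.2 0.3 0.5 0.7 1.0 1.4 1.8 2.2 2.6 3.0 3.5 4.0  (Å²)

— 13 values, denser at low `B_iso` where the surface is most strongly
curved in B and linear interpolation is least reliable.  Intermediate
`B_iso` evaluates the two bracketing node curves at the exact `s` and
interpolates linearly in B; out-of-range `B_iso` raises rather than
extrapolates; `s > 6 Å⁻¹` returns zero for the absorptive part.

Quality gate: the fitted curve must stay within 0.1% of the direct value
at every grid point where the direct value exceeds 1e-3 of its maximum.
Below that floor relative error is meaningless (the curve is passing
through zero on a finite grid) and errors there are suppressed in use by
`exp(−B s²)`.

Numerical strategy, in order of what mattered:

* **Relative weighting.**  Unweighted least squares puts all its accuracy
  at the peak; the gate is relative over three decades.  Gated points are
  weighted `1/max(y, floor)`.
* **Signed amplitudes.**  With `a_i ≥ 0` the gate is unreachable (best
  ~0.3 relative): tracking three decades next to the clamped zero region
  requires a slowly varying negative component cancelling against the
  constant.  Amplitudes are free in sign; widths are bounded in
  `[1e-4, 1e3] Å²`; the evaluated-then-clamped curve is non-negative by
  construction regardless.
* **Soft tail control.**  Sub-floor points (including the clamped zeros)
  get a small weight `alpha/floor`, with `alpha` relaxed through
  {2e-2, 2e-3, 2e-4, 0} until the gate passes.  This keeps the spurious
  model tail beyond the zero crossing as small as the gate allows (the
  error maps confirm the residual tail stays well inside the 1% weighted
  ceiling).
* **Variable projection + analytic Jacobian.**  The model is linear in the
  amplitudes and constant, so the trust-region-reflective search runs over
  the four log-widths with the linear part solved exactly, followed by a
  full 9-parameter polish with an analytic Jacobian.  Width starts are
  log-spaced over the curve's support; all initialization is
  deterministic, so identical configurations give byte-identical tables.
* **Minimax refinement.**  Least squares minimizes the sum of squares; the
  gate caps the maximum.  When the margin is thin, a Lawson-style
  iteratively-reweighted pass (up-weighting the worst points) pushes the
  solution toward the discrete minimax, with an SLSQP minimax solve as a
  last resort.
* **Warm starts.**  Tables are built from high `B_iso` (easy) to low, each
  node seeded by its neighbour's solution and accepted soft-weight stage.

### Known limitations

* **Li and Be at low B_iso.**  The absorptive curves of Li
  (B = 0.2–1.0 Å²) and Be (B = 0.2–0.7 Å²) have a sharp low-s feature over
  a broad three-decade decay that four Gaussians plus a constant cannot
  track to 0.1%: the *global* minimax over the gated grid is 1.02–1.21e-3,
  established by multi-start variable projection, Lawson iteration, SLSQP
  minimax and differential evolution, unchanged under fully converged
  quadrature, and worse under an independent Mott–Bethe Born backend.  The
  gate is enforced strictly, so a full periodic-table build records these
  two elements as failures (101 of 103 elements stored).  All other
  elements, including H and the synthetic heavy stand-ins, pass with
  margin.
* The fit targets the clamped curve; beyond the zero crossing the model
  may carry a small positive tail (fractions of a percent to a few percent
  of the peak at the lowest B_iso nodes).  It is invisible under the
  temperature factor — the weighted, normalized error maps stay below ~0.5%
  — but the parameterized `beta f'` should not be used unweighted deep in
  the clamped region.
* Anisotropic displacement parameters, ionic/multipolar scattering
  factors, plasmon/core-loss absorption and n-beam TDS redistribution are
  out of scope; `f'` here is the two-beam Einstein-model TDS part only.

## Structure factors

`F_g = Σ occ_n (gamma f + i gamma f') e^(−B_n s²) e^(−2πi g·r_n)` with
`s = 1/(2 d_hkl)` from the cell metric (via gemmi).  The phase sign
convention is `exp(−2πi h·x)`, fixed package-wide; only consistency
matters for `|F|²`.  CIF input is the minimal P1 dialect (cell, atom-site
loop, `B_iso` or `U_iso` with `B = 8π²U`, occupancy defaulting to 1);
symmetry expansion is deliberately not performed.  Setting the absorptive
table to zero reduces `F_g` to the kinematic structure factor exactly
(verified), and body-centred extinctions hold to 1e-12 with absorption
included.

## Validation surfaces and problem sizes

Error maps evaluate `exp(−B s²) |beta f'_param − beta f'_direct|`,
normalized by the map maximum of the weighted direct value, on default
grids of 31 × 21 (s ∈ [0, 3], B ∈ [0.1, 4]); grid points where the direct
clamped value is zero are flagged blank.  At-node rows carry only the fit
residual; off-node values are dominated by the linear-B interpolation and
stay below ~0.5% of the weighted maximum for C, Ga and Pb (1% is the
default gate ceiling).  Off-node spot checks against the direct integral
agree to a few parts in 10³ where the factor is large.

The test suite and the acceptance script size their runs for a single CPU:
survey quadrature for bulk builds, the C/Ga/Pb trio for accuracy checks,
25 × 17 error maps, and one full 103-element build (~5–6 minutes).  Speed
figures (parameterized evaluation ~0.5 µs, ~10³× faster than the direct
integral at survey settings) are hardware-dependent and only a
conservative 100× floor is asserted.
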