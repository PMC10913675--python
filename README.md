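# edafs — parameterized absorptive electron scattering factors

Structure refinement against three-dimensional electron diffraction
(3D-ED / microED / cRED) data increasingly relies on dynamical (Bloch-wave)
simulation of intensities.  Electrons scattered by phonons leave the Bragg
beams and end up in a broad thermal diffuse background; in a two-beam
Einstein model this loss is described by giving every atom a complex
scattering factor

    gamma f(s) + i gamma f'(s),        s = sin(theta) / lambda = g / 2,

where `f` is the Born electron scattering factor, `f'` the absorptive part
driven by the isotropic Debye–Waller factor `B_iso`, and `gamma`, `beta =
v/c` come from the accelerating voltage.  The voltage-independent product
`beta * f'(s, B_iso)` is a 2-D integral over the Ewald sphere — too slow to
evaluate inside a refinement loop.

`edafs` computes that integral directly (the ground-truth path), compresses
it per element into

    beta f'(s) ≈ a1 e^(-b1 s²) + a2 e^(-b2 s²) + a3 e^(-b3 s²) + a4 e^(-b4 s²) + c

at 13 `B_iso` nodes spanning 0.1–4 Å² (9 × 13 = 117 numbers per element,
linear interpolation in `B_iso` in between, negative values clamped to
zero), and assembles complex structure factors

    F_g = Σ_n occ_n [gamma f_n + i gamma f'_n] exp(-B_n s²) exp(-2πi g·r_n)

for P1 crystal models read from a minimal CIF dialect.  It is intended for
developers of electron-diffraction refinement and simulation codes who need
absorptive factors at refinement-loop speed, across the periodic table.

Born factors use the 5-Gaussian electron scattering parameterization
shipped with `gemmi` (Z = 1–98) plus a clearly-labelled synthetic
extrapolation for Es–Lr; the Lobato–Van Dyck rational-Gaussian form is
supported as a drop-in backend for user-supplied coefficient files.

## Worked example

```python
import numpy as np
import edafs

# fit the 13-node table for carbon from the direct integral (a few seconds)
table = edafs.build_table([6], config=edafs.SURVEY_CONFIG)
print(f"worst fit residual: {table.max_residual():.2e}")

s = np.array([0.0, 0.25, 0.5, 1.0])
fac = edafs.complex_scattering_factor(table, "C", s, b_iso=1.2, voltage=200e3)
for si, re_, im_ in zip(s, fac.real, fac.imag):
    print(f"{si:6.2f} {re_:10.4f} {im_:10.4f}")
```

prints

```
worst fit residual: 7.16e-04
  0.00     3.4907     0.0212
  0.25     1.6259     0.0164
  0.50     0.5755     0.0087
  1.00     0.1633     0.0011
```

Every fitted node reproduced the direct integral to better than 0.1%
(worst 7.2e-4).  The columns are `gamma*f` and `gamma*f'` in Å for carbon
at `B_iso = 1.2 Å²` and 200 kV (`gamma = 1.39139`, `beta = 0.69531`): the
absorptive part is two orders of magnitude below the elastic part for this
light atom (for Pb the ratio is about 13) and dies off faster with angle.

The same operations are available from the shell:

```sh
edafs fit-table --elements C,Ga,Pb --survey --out table.json
edafs eval C --s 0,0.25,0.5 --b-iso 1.2 --voltage 200000 --table table.json
edafs validate C --table table.json
edafs sf crystal.cif --hkl-max 3 --voltage 200000 --table table.json --out refl.txt
```

`validate` re-integrates the direct factor on an (s, B_iso) grid and checks
both quality gates (0.1% at-node accuracy; a 1% ceiling on the
temperature-factor-weighted interpolation error, normalized by the largest
weighted factor on the map), exiting non-zero on failure.

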