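import numpy as np
import pytest

import edafs


@pytest.fixture(scope="session")
def ref_table() -> edafs.ParameterTable:
    """Survey-quality parameter table for a light/intermediate/heavy trio."""
    table = edafs.build_table([6, 31, 82], config=edafs.SURVEY_CONFIG)
    assert not table.failures
    return table


@pytest.fixture(scope="session")
def gaussian_atom() -> edafs.GaussianAtom:
    return edafs.GaussianAtom(amplitude=3.0, width=1.5)


@pytest.fixture()
def bcc_carbon() -> edafs.CrystalModel:
    """Two identical atoms at (0,0,0) and (1/2,1/2,1/2): body-centred toy cell."""
    return edafs.CrystalModel(
        cell=(4.0, 4.0, 4.0, 90.0, 90.0, 90.0),
        sites=[
            edafs.AtomSite(element=6, frac_xyz=(0.0, 0.0, 0.0), b_iso=1.0),
            edafs.AtomSite(element=6, frac_xyz=(0.5, 0.5, 0.5), b_iso=1.0),
        ],
    )


@pytest.fixture()
def minimal_cif(tmp_path):
    """Smallest valid CIF: P1 cell with one carbon at the origin."""
    text = """\
data_toy
_cell_length_a 5.0
_cell_length_b 6.0
_cell_length_c 7.0
_cell_angle_alpha 90.0
_cell_angle_beta 90.0
_cell_angle_gamma 90.0
loop_
_atom_site_label
_atom_site_type_symbol
_atom_site_fract_x
_atom_site_fract_y
_atom_site_fract_z
_atom_site_B_iso_or_equiv
C1 C 0.0 0.0 0.0 1.0
"""
    path = tmp_path / "toy.cif"
    path.write_text(text)
    return path


def make_node(z: int, b_iso: float, a, b, c: float) -> edafs.GaussianSumParams:
    return edafs.GaussianSumParams(
        atomic_number=z, b_iso=b_iso, a=tuple(a), b=tuple(b), c=c, max_rel_residual=0.0
    )


@pytest.fixture()
def zero_table() -> edafs.ParameterTable:
    """A table whose absorptive part is identically zero (kinematic limit)."""
    grid = (0.1, 4.0)
    table = edafs.ParameterTable(b_iso_grid=grid)
    for z in (6, 31, 82):
        table.entries[z] = [
            make_node(z, b, (0.0, 0.0, 0.0, 0.0), (0.1, 1.0, 10.0, 100.0), 0.0)
            for b in grid
        ]
    return table
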