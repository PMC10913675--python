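import math

import numpy as np
import pytest

from edafs.fast_eval import complex_scattering_factor
from edafs.kinematics import beam_parameters
from edafs.structure import (
    AtomSite,
    CrystalModel,
    U_TO_B,
    read_cif,
    reflection_list,
    structure_factor,
    write_reflection_list,
)


class TestReadCif:
    def test_minimal_p1_cif(self, minimal_cif):
        model = read_cif(minimal_cif)
        assert model.cell == (5.0, 6.0, 7.0, 90.0, 90.0, 90.0)
        assert len(model.sites) == 1
        site = model.sites[0]
        assert site.element == 6
        assert site.b_iso == 1.0
        assert site.occupancy == 1.0  # column absent -> default

    def test_u_iso_conversion(self, tmp_path):
        text = """\
data_u
_cell_length_a 5
_cell_length_b 5
_cell_length_c 5
_cell_angle_alpha 90
_cell_angle_beta 90
_cell_angle_gamma 90
loop_
_atom_site_label
_atom_site_fract_x
_atom_site_fract_y
_atom_site_fract_z
_atom_site_U_iso_or_equiv
_atom_site_occupancy
C1 0 0 0 0.0127 0.5
"""
        path = tmp_path / "u.cif"
        path.write_text(text)
        model = read_cif(path)
        assert model.sites[0].b_iso == pytest.approx(U_TO_B * 0.0127, rel=1e-12)
        assert model.sites[0].b_iso == pytest.approx(1.0027, abs=2e-4)
        assert model.sites[0].occupancy == 0.5

    def test_missing_cell_tag_is_named(self, tmp_path):
        path = tmp_path / "bad.cif"
        path.write_text("data_x\n_cell_length_a 5\n")
        with pytest.raises(ValueError, match="_cell_length_b"):
            read_cif(path)

    def test_missing_displacement_column(self, tmp_path):
        path = tmp_path / "nob.cif"
        path.write_text("""\
data_x
_cell_length_a 5
_cell_length_b 5
_cell_length_c 5
_cell_angle_alpha 90
_cell_angle_beta 90
_cell_angle_gamma 90
loop_
_atom_site_label
_atom_site_fract_x
_atom_site_fract_y
_atom_site_fract_z
C1 0 0 0
""")
        with pytest.raises(ValueError, match="B_iso_or_equiv"):
            read_cif(path)

    def test_unknown_element(self, tmp_path):
        path = tmp_path / "elt.cif"
        path.write_text("""\
data_x
_cell_length_a 5
_cell_length_b 5
_cell_length_c 5
_cell_angle_alpha 90
_cell_angle_beta 90
_cell_angle_gamma 90
loop_
_atom_site_label
_atom_site_type_symbol
_atom_site_fract_x
_atom_site_fract_y
_atom_site_fract_z
_atom_site_B_iso_or_equiv
Q1 Qq 0 0 0 1.0
""")
        with pytest.raises(LookupError, match="Qq"):
            read_cif(path)


class TestGeometry:
    def test_s_from_orthorhombic_metric(self):
        model = CrystalModel(
            cell=(4.0, 5.0, 8.0, 90.0, 90.0, 90.0),
            sites=[AtomSite(6, (0, 0, 0), 1.0)],
        )
        h, k, l = 1, 2, 3
        manual = 0.5 * math.sqrt((h / 4.0) ** 2 + (k / 5.0) ** 2 + (l / 8.0) ** 2)
        assert model.s_of_hkl((h, k, l)) == pytest.approx(manual, rel=1e-12)
        assert model.s_of_hkl((0, 0, 0)) == 0.0

    def test_invalid_models(self):
        with pytest.raises(ValueError, match="at least one"):
            CrystalModel(cell=(4, 4, 4, 90, 90, 90), sites=[])
        with pytest.raises(ValueError):
            AtomSite(6, (0, 0, 0), b_iso=-1.0)
        with pytest.raises(ValueError):
            AtomSite(6, (0, 0, 0), b_iso=1.0, occupancy=1.5)


class TestStructureFactor:
    def test_single_atom_at_origin_has_no_phase(self, ref_table):
        model = CrystalModel(
            cell=(4.0, 4.0, 4.0, 90.0, 90.0, 90.0),
            sites=[AtomSite(6, (0.0, 0.0, 0.0), 1.0)],
        )
        for hkl in ((1, 0, 0), (1, 1, 0), (2, 1, 3)):
            s = model.s_of_hkl(hkl)
            fac = complex_scattering_factor(ref_table, 6, s, 1.0, 200e3)
            expected = complex(float(fac.real), float(fac.imag)) * math.exp(-1.0 * s * s)
            F = structure_factor(model, hkl, ref_table, 200e3)
            assert F == pytest.approx(expected, rel=1e-12)

    def test_body_centring_extinction(self, ref_table, bcc_carbon):
        for hkl in ((1, 0, 0), (1, 1, 1), (2, 1, 0)):
            assert sum(hkl) % 2 == 1
            F = structure_factor(bcc_carbon, hkl, ref_table, 200e3)
            assert abs(F) <= 1e-12
        F_allowed = structure_factor(bcc_carbon, (1, 1, 0), ref_table, 200e3)
        assert abs(F_allowed) > 0.1

    def test_friedel_pairs_for_centrosymmetric_model(self, ref_table):
        model = CrystalModel(
            cell=(6.0, 6.0, 6.0, 90.0, 90.0, 90.0),
            sites=[
                AtomSite(31, (0.13, 0.27, 0.41), 0.8),
                AtomSite(31, (-0.13, -0.27, -0.41), 0.8),
            ],
        )
        for hkl in ((1, 0, 0), (1, 2, 1), (3, 1, 2)):
            F_plus = structure_factor(model, hkl, ref_table, 200e3)
            F_minus = structure_factor(model, tuple(-v for v in hkl), ref_table, 200e3)
            assert abs(F_plus) == pytest.approx(abs(F_minus), rel=1e-10)

    def test_zero_absorptive_table_reduces_to_kinematic(self, zero_table, bcc_carbon):
        from edafs.born import born_factor

        hkl = (1, 1, 0)
        s = bcc_carbon.s_of_hkl(hkl)
        gamma = beam_parameters(200e3).gamma
        F = structure_factor(bcc_carbon, hkl, zero_table, 200e3)
        expected = 2.0 * gamma * float(born_factor(6, s)) * math.exp(-1.0 * s * s)
        assert F.imag == pytest.approx(0.0, abs=1e-14)
        assert F.real == pytest.approx(expected, rel=1e-12)

    def test_forward_beam_sums_all_sites(self, ref_table):
        model = CrystalModel(
            cell=(5.0, 5.0, 5.0, 90.0, 90.0, 90.0),
            sites=[
                AtomSite(6, (0.1, 0.2, 0.3), 1.0, occupancy=0.7),
                AtomSite(82, (0.6, 0.4, 0.9), 2.2),
            ],
        )
        F0 = structure_factor(model, (0, 0, 0), ref_table, 200e3)
        expected = 0.0 + 0.0j
        for site in model.sites:
            fac = complex_scattering_factor(ref_table, site.element, 0.0, site.b_iso, 200e3)
            expected += site.occupancy * complex(float(fac.real), float(fac.imag))
        assert F0 == pytest.approx(expected, rel=1e-12)

    def test_out_of_range_site_b_identifies_site(self, ref_table):
        model = CrystalModel(
            cell=(4.0, 4.0, 4.0, 90.0, 90.0, 90.0),
            sites=[AtomSite(6, (0, 0, 0), 9.0, label="C_big")],
        )
        with pytest.raises(ValueError, match="C_big"):
            structure_factor(model, (1, 0, 0), ref_table, 200e3)


def test_reflection_list_output(tmp_path, ref_table, bcc_carbon):
    refl = reflection_list(bcc_carbon, 1, ref_table, 200e3)
    assert len(refl) == 26  # 3^3 - 1
    path = tmp_path / "refl.txt"
    write_reflection_list(path, refl)
    lines = path.read_text().splitlines()
    assert lines[0].lstrip("#").split() == ["h", "k", "l", "s", "Re(F)", "Im(F)", "|F|^2"]
    assert len(lines) == 27
    cols = lines[1].split()
    assert len(cols) == 7
    float(cols[4]), float(cols[5]), float(cols[6])  # parseable numbers
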