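import numpy as np
import pytest

from edafs.integral import SURVEY_CONFIG
from edafs.parameterization import (
    DEFAULT_B_GRID,
    DEFAULT_S_GRID,
    FitError,
    GaussianSumParams,
    ParameterTable,
    build_table,
    fit_node,
    sample_curve,
)


def make_truth(a, b, c):
    return GaussianSumParams(
        atomic_number=6, b_iso=1.0, a=tuple(a), b=tuple(b), c=c, max_rel_residual=0.0
    )


class TestFitNode:
    @pytest.mark.parametrize(
        "a,b,c",
        [
            ((0.4, 1.2, 0.8, 0.05), (0.3, 2.0, 8.0, 40.0), 0.002),
            ((0.1, 0.3, 0.6, 0.2), (0.15, 1.0, 5.0, 25.0), 0.0005),
        ],
    )
    def test_recovers_own_model_family(self, a, b, c):
        """A curve generated by the model itself is reproduced to 1e-10 on-grid."""
        truth = make_truth(a, b, c)
        y = truth.evaluate(DEFAULT_S_GRID)
        assert np.all(y > 0)
        fitted = fit_node(6, 1.0, curve=y)
        recon = fitted.evaluate(DEFAULT_S_GRID)
        assert np.max(np.abs(recon - y) / y) <= 1e-10

    def test_all_zero_curve_gives_zero_params(self):
        fitted = fit_node(6, 0.0, curve=np.zeros_like(DEFAULT_S_GRID))
        assert fitted.a == (0.0, 0.0, 0.0, 0.0)
        assert fitted.c == 0.0
        assert fitted.max_rel_residual == 0.0
        assert np.all(fitted.evaluate(DEFAULT_S_GRID) == 0.0)

    def test_carbon_node_meets_residual_gate(self):
        fitted = fit_node(6, 1.0, config=SURVEY_CONFIG)
        assert fitted.max_rel_residual <= 1e-3
        # independent re-check of the recorded residual
        y = sample_curve(6, 1.0, config=SURVEY_CONFIG)
        mask = y >= 1e-3 * y.max()
        recon = fitted.evaluate(DEFAULT_S_GRID)
        assert np.max(np.abs(recon[mask] - y[mask]) / y[mask]) <= 1e-3

    def test_unfittable_curve_raises_with_profile(self):
        s = DEFAULT_S_GRID
        y = 0.5 + np.abs(np.sin(9.0 * s))  # oscillatory: far outside the family
        with pytest.raises(FitError) as excinfo:
            fit_node(6, 1.0, curve=y)
        assert excinfo.value.residual_profile.shape == s.shape
        assert excinfo.value.residual_profile.max() > 1e-3

    def test_too_few_nondegenerate_points(self):
        y = np.zeros_like(DEFAULT_S_GRID)
        y[:5] = [0.5, 0.4, 0.3, 0.2, 0.1]
        with pytest.raises(FitError, match="non-degenerate"):
            fit_node(6, 1.0, curve=y)


class TestSampleCurve:
    def test_zero_b_iso_gives_zero_vector(self):
        y = sample_curve(6, 0.0, config=SURVEY_CONFIG)
        assert y.shape == DEFAULT_S_GRID.shape
        assert np.all(y == 0.0)

    def test_matches_gaussian_closed_form(self, gaussian_atom):
        """The sampling path agrees with the analytic oracle for a mock atom."""
        from edafs.born import BornCoefficients
        from edafs.integral import gaussian_atom_closed_form

        class MockTable:
            def coefficients(self, z):
                return BornCoefficients(
                    atomic_number=z,
                    symbol="Mock",
                    a=(gaussian_atom.amplitude, 0.0, 0.0, 0.0, 0.0),
                    b=(gaussian_atom.width, 1.0, 1.0, 1.0, 1.0),
                    source="mock",
                )

        s_grid = np.array([0.0, 0.5, 1.0, 2.0])
        y = sample_curve(6, 1.0, s_grid=s_grid, born_table=MockTable())
        exact = np.maximum(
            gaussian_atom_closed_form(
                gaussian_atom.amplitude, gaussian_atom.width, s_grid, 1.0
            ),
            0.0,
        )
        assert np.allclose(y, exact, rtol=1e-6, atol=1e-15)

    def test_heavy_atom_high_b_tail_is_clamped_to_zero(self):
        y = sample_curve(82, 4.0, config=SURVEY_CONFIG)
        assert np.all(y[DEFAULT_S_GRID >= 2.0] == 0.0)
        assert y[0] > 0


class TestParameterTable:
    def test_single_element_counts(self, ref_table):
        assert len(ref_table.nodes(6)) == len(DEFAULT_B_GRID) == 13
        assert ref_table.n_parameters(6) == 117
        for node in ref_table.nodes(6):
            assert node.max_rel_residual <= 1e-3

    def test_roundtrip_and_determinism(self, tmp_path):
        t1 = build_table([6], b_iso_grid=(0.5, 1.0), s_grid=np.linspace(0, 6, 40),
                         config=SURVEY_CONFIG)
        t2 = build_table([6], b_iso_grid=(0.5, 1.0), s_grid=np.linspace(0, 6, 40),
                         config=SURVEY_CONFIG)
        assert t1.to_json() == t2.to_json()
        path = tmp_path / "table.json"
        t1.save(path)
        loaded = ParameterTable.load(path)
        assert loaded.to_json() == t1.to_json()
        assert loaded.b_iso_grid == (0.5, 1.0)
        node = loaded.nodes(6)[0]
        assert node.b == t1.nodes(6)[0].b

    def test_empty_element_list_is_valid(self, tmp_path):
        table = build_table([], config=SURVEY_CONFIG)
        assert table.elements == []
        assert table.complete
        path = tmp_path / "empty.json"
        table.save(path)
        assert ParameterTable.load(path).elements == []

    def test_unknown_major_version_rejected(self, tmp_path):
        table = build_table([], config=SURVEY_CONFIG)
        path = tmp_path / "bad.json"
        path.write_text(table.to_json().replace('"format_version": "1.0"',
                                                '"format_version": "2.0"'))
        with pytest.raises(ValueError, match="format version"):
            ParameterTable.load(path)

    def test_missing_element_lookup(self, ref_table):
        with pytest.raises(LookupError):
            ref_table.nodes(7)

    def test_grid_must_ascend(self):
        with pytest.raises(ValueError, match="ascending"):
            build_table([6], b_iso_grid=(1.0, 0.5), config=SURVEY_CONFIG)

    def test_checkpoint_resume(self, tmp_path):
        kwargs = dict(
            b_iso_grid=(0.5, 1.0), s_grid=np.linspace(0, 6, 40),
            config=SURVEY_CONFIG, checkpoint_dir=tmp_path / "ckpt",
        )
        t1 = build_table([6], **kwargs)
        t2 = build_table([6], **kwargs)  # second run resumes from checkpoint
        assert t1.to_json() == t2.to_json()

    def test_params_validation(self):
        with pytest.raises(ValueError):
            GaussianSumParams(6, 1.0, (1.0, 1.0, 1.0), (1.0, 1.0, 1.0), 0.0)
        with pytest.raises(ValueError):
            GaussianSumParams(6, 1.0, (1.0,) * 4, (1.0, 1.0, 1.0, -2.0), 0.0)
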