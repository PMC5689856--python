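"""Core types: CT->ED conversion, material blending, grid I/O."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import ccdose as cc
from ccdose.core_model import ConfigurationError, FormatError, Grid3D, Structure, StructureSet

TABLE = cc.CTtoEDTable(np.array([[-1000.0, 0.0], [0.0, 1.0], [1000.0, 2.0]]))


def _hu_grid(values):
    arr = np.asarray(values, dtype=float).reshape(1, 1, -1)
    return Grid3D([1.0, 1.0, 1.0], [0.0, 0.0, 0.0], arr)


class TestHuToDensity:
    @pytest.mark.parametrize(
        "hu, expected",
        [(0.0, 1.0), (-2000.0, 0.0), (500.0, 1.5), (2000.0, 2.0), (-1000.0, 0.0)],
    )
    def test_interpolation_and_clamping(self, hu, expected):
        vol = cc.hu_to_density(_hu_grid([hu]), TABLE)
        assert vol.ed[0, 0, 0] == pytest.approx(expected)

    def test_override_structure_wins_over_hu(self):
        ct = _hu_grid([0.0, 0.0])
        mask = np.array([[[True, False]]])
        ss = StructureSet([Structure("cavity", mask, density_override=0.05)])
        vol = cc.hu_to_density(ct, TABLE, overrides=ss)
        assert vol.ed[0, 0, 0] == pytest.approx(0.05)
        assert vol.ed[0, 0, 1] == pytest.approx(1.0)

    def test_body_structure_defines_mask(self):
        ct = _hu_grid([0.0, 0.0])
        ss = StructureSet([Structure("body", np.array([[[True, False]]]))])
        vol = cc.hu_to_density(ct, TABLE, overrides=ss)
        assert vol.body_mask.tolist() == [[[True, False]]]

    def test_invalid_tables_rejected(self):
        with pytest.raises(ConfigurationError):
            cc.CTtoEDTable(np.array([[0.0, 1.0]]))
        with pytest.raises(ConfigurationError):
            cc.CTtoEDTable(np.array([[0.0, 1.0], [-10.0, 0.5]]))

    @given(
        hu_pair=st.tuples(
            st.floats(-1500, 2500, allow_nan=False), st.floats(-1500, 2500, allow_nan=False)
        )
    )
    def test_monotone_in_hu(self, hu_pair):
        lo, hi = sorted(hu_pair)
        vol = cc.hu_to_density(_hu_grid([lo, hi]), TABLE)
        assert vol.ed[0, 0, 0] <= vol.ed[0, 0, 1] + 1e-12


class TestMaterialBlend:
    def test_water_node_exact(self, materials):
        mu, muen = cc.material_blend(1.0, materials)
        np.testing.assert_allclose(mu, materials.water.mu_over_rho)
        np.testing.assert_allclose(muen, materials.water.muen_over_rho)

    def test_nine_materials_with_water(self, materials):
        assert len(materials.materials) == 9
        assert any(m.name == "water" for m in materials.materials)

    def test_clamps_outside_range(self, materials):
        lo = materials.materials[0]
        hi = materials.materials[-1]
        mu_lo, _ = cc.material_blend(0.0, materials)
        mu_hi, _ = cc.material_blend(99.0, materials)
        np.testing.assert_allclose(mu_lo, lo.mu_over_rho)
        np.testing.assert_allclose(mu_hi, hi.mu_over_rho)

    def test_midpoint_is_arithmetic_mean(self, materials):
        a, b = materials.materials[3], materials.materials[4]
        mid = (a.reference_ed + b.reference_ed) / 2.0
        mu, muen = cc.material_blend(mid, materials)
        np.testing.assert_allclose(mu, (a.mu_over_rho + b.mu_over_rho) / 2.0)
        np.testing.assert_allclose(muen, (a.muen_over_rho + b.muen_over_rho) / 2.0)

    @given(ed=st.floats(0.0, 4.0, allow_nan=False))
    def test_continuous_in_ed(self, ed, materials):
        eps = 1e-6
        mu1, _ = cc.material_blend(ed, materials)
        mu2, _ = cc.material_blend(ed + eps, materials)
        assert np.max(np.abs(mu1 - mu2)) < 1e-4

    def test_negative_ed_rejected(self, materials):
        with pytest.raises(ValueError):
            cc.material_blend(-0.1, materials)


class TestGridIO:
    def _grid(self):
        rng = np.random.default_rng(7)
        return Grid3D([2.5, 2.5, 3.0], [-10.0, 5.0, -20.0], rng.random((10, 10, 10)), unit="Gy")

    def test_internal_round_trip(self, tmp_path):
        g = self._grid()
        path = tmp_path / "dose.ccd"
        cc.write_dose_grid(g, path)
        back = cc.read_dose_grid(path)
        assert back.dims == g.dims
        np.testing.assert_allclose(back.spacing, g.spacing)
        np.testing.assert_allclose(back.origin, g.origin)
        assert np.max(np.abs(back.values - g.values)) <= 1e-6 * g.values.max()

    def test_rtdose_round_trip(self, tmp_path):
        g = self._grid()
        path = tmp_path / "dose.dcm"
        cc.write_dose_grid(g, path)
        back = cc.read_dose_grid(path)
        assert back.dims == g.dims
        np.testing.assert_allclose(back.spacing, g.spacing)
        np.testing.assert_allclose(back.origin, g.origin)
        assert np.max(np.abs(back.values - g.values)) <= 1e-6 * g.values.max()

    def test_dose_grid_scaling_honored(self, tmp_path):
        import pydicom

        g = Grid3D([1.0, 1.0, 1.0], [0.0, 0.0, 0.0], np.full((2, 2, 2), 2.0))
        path = tmp_path / "scaled.dcm"
        cc.write_dose_grid(g, path)
        ds = pydicom.dcmread(str(path))
        ds.DoseGridScaling = 0.001
        ds.PixelData = np.full(8, 2000, dtype="<u4").tobytes()
        ds.save_as(str(path))
        back = cc.read_dose_grid(path)
        np.testing.assert_allclose(back.values, 2.0)

    def test_nonuniform_frame_offsets_rejected(self, tmp_path):
        import pydicom

        g = Grid3D([1.0, 1.0, 1.0], [0.0, 0.0, 0.0], np.ones((2, 2, 3)))
        path = tmp_path / "bad.dcm"
        cc.write_dose_grid(g, path)
        ds = pydicom.dcmread(str(path))
        ds.GridFrameOffsetVector = [0.0, 1.0, 3.5]
        ds.save_as(str(path))
        with pytest.raises(FormatError, match="GridFrameOffsetVector"):
            cc.read_dose_grid(path)

    def test_missing_geometry_tag_named_in_error(self, tmp_path):
        import pydicom

        g = Grid3D([1.0, 1.0, 1.0], [0.0, 0.0, 0.0], np.ones((2, 2, 2)))
        path = tmp_path / "missing.dcm"
        cc.write_dose_grid(g, path)
        ds = pydicom.dcmread(str(path))
        del ds.DoseGridScaling
        ds.save_as(str(path))
        with pytest.raises(FormatError, match="DoseGridScaling"):
            cc.read_dose_grid(path)

    def test_missing_file(self):
        with pytest.raises(FileNotFoundError):
            cc.read_dose_grid("/nonexistent/grid.ccd")


class TestGridValidation:
    def test_rejects_bad_geometry(self):
        with pytest.raises(ValueError):
            Grid3D([0.0, 1.0, 1.0], [0.0, 0.0, 0.0], np.ones((2, 2, 2)))
        with pytest.raises(ValueError):
            Grid3D([1.0, 1.0, 1.0], [0.0, 0.0, 0.0], np.array([[[np.inf]]]))

    def test_trilinear_sampling_matches_centers(self):
        g = Grid3D([2.0, 2.0, 2.0], [0.0, 0.0, 0.0], np.arange(8.0).reshape(2, 2, 2))
        assert g.sample(np.array([0.0, 0.0, 2.0])) == pytest.approx(1.0)
        assert g.sample(np.array([1.0, 0.0, 0.0])) == pytest.approx(2.0)  # midpoint x
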