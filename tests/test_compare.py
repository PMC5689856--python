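"""Gamma analysis, depth-dose extraction, ROI mean, surface exclusion, reports."""

import numpy as np
import pytest

import ccdose as cc
from ccdose.compare import report_text
from ccdose.core_model import Grid3D
from conftest import make_gamma_pair

CRIT3 = cc.GammaCriteria(3.0, 2.0, "global", 10.0)
CRIT2 = cc.GammaCriteria(2.0, 2.0, "global", 10.0)


class TestGammaBasics:
    def test_identity_gives_zero_gamma_and_full_pass(self):
        ref, _ = make_gamma_pair(3)
        res = cc.gamma_analysis(ref, ref, CRIT3)
        vals = res.gamma_map.values
        assert np.nanmax(vals) == 0.0
        assert res.passing_rate == 100.0

    def test_uniform_scaled_by_criterion_hits_gamma_one(self):
        """A uniform field scaled by exactly (1 + dose_pct/100) sits on the
        criterion boundary: gamma = 1 everywhere under global normalization
        (no spatial offset can reduce a uniform difference)."""
        ref = Grid3D([2.5] * 3, [0, 0, 0], np.full((10, 10, 10), 2.0))
        ev = Grid3D([2.5] * 3, [0, 0, 0], np.full((10, 10, 10), 2.0 * 1.03))
        res = cc.gamma_analysis(ref, ev, CRIT3)
        np.testing.assert_allclose(res.gamma_map.values, 1.0, atol=1e-9)

    def test_low_dose_cutoff_excludes_voxels(self):
        vals = np.full((8, 8, 8), 0.05)
        vals[4, 4, 4] = 1.0
        ref = Grid3D([2.5] * 3, [0, 0, 0], vals)
        res = cc.gamma_analysis(ref, ref, CRIT3)
        assert res.n_evaluated == 1  # everything below 10% of max excluded

    def test_disjoint_grids_rejected(self):
        a = Grid3D([1.0] * 3, [0, 0, 0], np.ones((4, 4, 4)))
        b = Grid3D([1.0] * 3, [500.0, 0, 0], np.ones((4, 4, 4)))
        with pytest.raises(ValueError, match="overlap"):
            cc.gamma_analysis(a, b, CRIT3)


class TestGammaBruteforce:
    def test_identity_full_pass(self):
        ref, _ = make_gamma_pair(5)
        res = cc.gamma_bruteforce(ref, ref, CRIT3)
        assert res.passing_rate == 100.0

    @pytest.mark.parametrize("shift_factor", [1.0, 2.0])
    def test_translated_gradient_matches_1d_closed_form(self, shift_factor):
        """A linear field rigidly translated by s has an exact gamma: the
        1D trade-off between the distance term (a = 1/dta) and the dose
        term (g = gradient/delta) minimizes to s * a * g / sqrt(a^2 + g^2),
        which approaches s/dta as the dose term dominates."""
        n = 81
        sp = 1.0
        x = np.arange(n) * sp
        grad = 2.0  # per mm
        vals = grad * x[:, None, None] + np.zeros((n, 9, 9))
        ref = Grid3D([sp] * 3, [0, 0, 0], vals)
        shift = shift_factor * CRIT3.dta_mm
        ev = Grid3D([sp] * 3, [shift, 0.0, 0.0], vals)  # same values, shifted frame
        res = cc.gamma_bruteforce(ref, ev, CRIT3)
        center = res.gamma_map.values[n // 2, 4, 4]
        a = 1.0 / CRIT3.dta_mm
        delta = CRIT3.dose_pct / 100.0 * vals.max()
        g = grad / delta
        expected = shift * a * g / np.hypot(a, g)
        assert center == pytest.approx(expected, abs=0.02)

    def test_refuses_large_grids(self):
        big = Grid3D([1.0] * 3, [0, 0, 0], np.ones((50, 50, 50)))
        with pytest.raises(ValueError, match="too large"):
            cc.gamma_bruteforce(big, big, CRIT3, max_voxels=10000)


class TestGammaProperties:
    def test_optimized_matches_bruteforce(self):
        worst = 0.0
        for seed in range(10):
            ref, ev = make_gamma_pair(seed)
            a = cc.gamma_analysis(ref, ev, CRIT3)
            b = cc.gamma_bruteforce(ref, ev, CRIT3)
            m = np.isfinite(a.gamma_map.values)
            assert np.array_equal(m, np.isfinite(b.gamma_map.values))
            worst = max(worst, np.abs(a.gamma_map.values[m] - b.gamma_map.values[m]).max())
        assert worst <= 0.01

    def test_rate_monotone_in_dose_criterion(self):
        for seed in range(5):
            ref, ev = make_gamma_pair(seed)
            r3 = cc.gamma_analysis(ref, ev, CRIT3).passing_rate
            r2 = cc.gamma_analysis(ref, ev, CRIT2).passing_rate
            assert r3 >= r2

    def test_global_rate_invariant_to_joint_scaling(self):
        ref, ev = make_gamma_pair(8)
        base = cc.gamma_analysis(ref, ev, CRIT3).passing_rate
        scaled = cc.gamma_analysis(
            ref.copy(values=ref.values * 37.5), ev.copy(values=ev.values * 37.5), CRIT3
        ).passing_rate
        assert scaled == pytest.approx(base, abs=1e-9)

    def test_symmetric_under_joint_translation(self):
        ref, ev = make_gamma_pair(9)
        a = cc.gamma_analysis(ref, ev, CRIT3)
        shift = np.array([13.0, -7.0, 4.0])
        ref2 = Grid3D(ref.spacing, ref.origin + shift, ref.values)
        ev2 = Grid3D(ev.spacing, ev.origin + shift, ev.values)
        b = cc.gamma_analysis(ref2, ev2, CRIT3)
        np.testing.assert_allclose(
            np.nan_to_num(a.gamma_map.values), np.nan_to_num(b.gamma_map.values), atol=1e-12
        )


class TestPDDExtraction:
    def _synthetic_dose(self):
        # analytic build-up/falloff curve on a grid: D(d) = d^2 e^{-d/60}
        g = cc.build_water_cube(150.0, spacing=2.5, center=(0, 0, -75.0)).grid
        depth = -g.voxel_centers()[..., 2]
        vals = (depth**2) * np.exp(-depth / 60.0)
        return Grid3D(g.spacing, g.origin, vals)

    def test_normalization_value_is_100(self):
        pdd = cc.extract_pdd(self._synthetic_dose(), (0, 0, 0), (0, 0, -1))
        assert pdd.at(pdd.normalization_depth) == pytest.approx(100.0, abs=1e-9)
        assert pdd.normalization_depth >= pdd.d_max + 20.0 - 1.0

    def test_flat_peak_resolves_to_shallowest_depth(self):
        g = Grid3D([1.0, 1.0, 1.0], [0.0, 0.0, -29.0], np.zeros((3, 3, 30)))
        depth = -g.axis_coords(2)  # 29 .. 0
        vals = np.where((depth >= 5) & (depth <= 10), 1.0, 0.5)
        g.values[:] = vals[None, None, :]
        pdd = cc.extract_pdd(g, (0, 0, 0), (0, 0, -1), normalization_depth=7.0)
        assert pdd.d_max <= 5.5

    def test_axis_outside_grid_rejected(self):
        with pytest.raises(ValueError, match="axis"):
            cc.extract_pdd(self._synthetic_dose(), (500.0, 0, 0), (0, 0, -1))

    def test_slab_pdd_shows_lung_dip_and_rebuild(self, slab_runs_15mv):
        """Small-field PDD on the slab phantom: dose drops inside the
        low-density lung (lost lateral equilibrium) and re-builds after
        the distal lung/water interface."""
        pdd = cc.extract_pdd(slab_runs_15mv["plain"], (0, 0, 0), (0, 0, -1))
        pre_interface = pdd.at(45.0)
        in_lung = np.mean([pdd.at(d) for d in (70, 80, 90)])
        assert in_lung < pre_interface
        post_min = min(pdd.at(d) for d in (100, 102, 104, 106))
        assert pdd.at(125.0) > post_min  # re-buildup in water


class TestROIMean:
    def test_uniform_dose(self):
        g = Grid3D([2.0] * 3, [-20.0] * 3, np.full((21, 21, 21), 2.0))
        assert cc.roi_mean(g, (0, 0, 0), 6.0) == pytest.approx(2.0)

    def test_linear_gradient_symmetric_roi(self):
        g = cc.build_water_cube(100.0, spacing=2.0).grid
        x = g.voxel_centers()[..., 0]
        dose = Grid3D(g.spacing, g.origin, 1.0 + 0.01 * x)
        center_val = float(dose.sample(np.zeros(3)))
        assert cc.roi_mean(dose, (0, 0, 0), 8.0) == pytest.approx(center_val, rel=1e-3)

    def test_matches_monte_carlo_volume_average(self):
        rng = np.random.default_rng(2)
        from scipy.ndimage import gaussian_filter

        g = cc.build_water_cube(80.0, spacing=2.0).grid
        dose = Grid3D(g.spacing, g.origin, gaussian_filter(rng.random(g.dims), 2.0) + 0.5)
        got = cc.roi_mean(dose, (3.0, -2.0, 5.0), 10.0)
        pts = rng.standard_normal((2_000_000, 3))
        pts = pts / np.linalg.norm(pts, axis=1)[:, None]
        radii = 10.0 * rng.random(2_000_000) ** (1 / 3)
        pts = pts * radii[:, None] + np.array([3.0, -2.0, 5.0])
        mc = dose.sample(pts, order=0).mean()
        assert got == pytest.approx(mc, rel=2e-3)

    def test_empty_or_outside_roi_rejected(self):
        g = Grid3D([2.0] * 3, [-20.0] * 3, np.ones((21, 21, 21)))
        with pytest.raises(ValueError):
            cc.roi_mean(g, (100.0, 0, 0), 5.0)


class TestSurfaceExclusion:
    def test_zero_margin_is_identity(self):
        mask = np.zeros((10, 10, 10), dtype=bool)
        mask[2:8, 2:8, 2:8] = True
        out = cc.surface_exclusion(mask, [2.0, 2.0, 2.0], 0.0)
        np.testing.assert_array_equal(out, mask)

    def test_sphere_erodes_to_smaller_sphere(self):
        g = cc.build_water_cube(140.0, spacing=2.0).grid
        r = np.linalg.norm(g.voxel_centers(), axis=-1)
        mask = r <= 50.0
        out = cc.surface_exclusion(mask, g.spacing, 7.0)
        expected = 4.0 / 3.0 * np.pi * 43.0**3 / 2.0**3
        assert abs(out.sum() - expected) / expected < 0.05

    def test_margin_larger_than_object_empties_mask(self):
        mask = np.zeros((10, 10, 10), dtype=bool)
        mask[4:6, 4:6, 4:6] = True
        out = cc.surface_exclusion(mask, [2.0, 2.0, 2.0], 10.0)
        assert not out.any()


class TestReport:
    def test_identity_comparison_row(self):
        ref, _ = make_gamma_pair(1)
        r3 = cc.gamma_analysis(ref, ref, CRIT3)
        r2 = cc.gamma_analysis(ref, ref, CRIT2)
        df = cc.report(
            [{"plan": "identity", "mode": "VMAT", CRIT2.label(): r2.passing_rate,
              CRIT3.label(): r3.passing_rate}]
        )
        assert df.iloc[0][CRIT3.label()] == 100.0
        assert df.iloc[0][CRIT2.label()] == 100.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            cc.report([])

    def test_text_output_rounds_to_tenth_percent(self):
        df = cc.report([{"plan": "p", "mode": "IMRT", "3%G/2 mm": 98.7654}])
        text = report_text(df)
        assert "98.8" in text and "98.7654" not in text
        # full precision retained in the frame itself
        assert df.iloc[0]["3%G/2 mm"] == 98.7654
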