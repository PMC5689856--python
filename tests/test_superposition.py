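"""Collapsed-cone superposition and plan-level orchestration."""

import numpy as np
import pytest

import ccdose as cc
from ccdose.beam_model import BeamGeometry
from ccdose.core_model import DensityVolume, Grid3D
from ccdose.kernels import KernelTable, build_cck, make_cone_set
from ccdose.superposition import superpose
from ccdose.terma import TermaGrid


def point_terma(n=121, spacing=1.0):
    g = Grid3D([spacing] * 3, [-(n - 1) * spacing / 2] * 3, np.ones((n, n, n)))
    vol = DensityVolume(g, np.ones(g.dims, dtype=bool))
    tv = np.zeros(g.dims)
    c = (n - 1) // 2
    tv[c, c, c] = 1.0
    tg = TermaGrid(
        Grid3D(g.spacing, g.origin, tv),
        np.full(g.dims, 2.0),
        np.zeros(g.dims),
        np.zeros(g.dims),
        BeamGeometry(0.0),
    )
    return vol, tg, c


def forward_exponential_cck(length_mm=12.0):
    """All kernel energy in the 0-1 degree zenith row, exponential radial
    profile: collectors on the beam axis see the pure radial kernel."""
    r_edges = np.arange(0.0, 61.0)
    th_edges = np.arange(0.0, 181.0)
    radial = np.exp(-r_edges[:-1] / length_mm) - np.exp(-r_edges[1:] / length_mm)
    k = np.zeros((180, 60))
    k[0] = radial / radial.sum()
    kern = KernelTable(th_edges, r_edges, k)
    edges = np.array([0.0, 1.0, 180.0])
    return build_cck(kern, zenith_edges_deg=edges), make_cone_set(edges, n_azimuth=6)


class TestPointKernelDeposition:
    def test_axis_dose_ratio_matches_kernel_bins(self):
        """Dose from a point-like TERMA along the forward cone axis falls
        off like the input kernel's radial bin masses (direct point-kernel
        summation oracle on a 1 mm grid)."""
        vol, tg, c = point_terma()
        cck, cones = forward_exponential_cck()
        mask = np.zeros(vol.grid.dims, dtype=bool)
        mask[c, c, :] = True
        dose = superpose(tg, vol, cck, cones, tilt=False, mask=mask)
        d10 = dose.values[c, c, c - 10]
        d20 = dose.values[c, c, c - 20]
        expected = cck.interval_mass(0, 9.5, 10.5) / cck.interval_mass(0, 19.5, 20.5)
        assert d10 / d20 == pytest.approx(expected, rel=0.05)

    def test_energy_conservation_for_contained_reach(self):
        """Sum(dose * mass) equals Sum(TERMA * mass) to 1% when the kernel
        reach is fully contained in the phantom."""
        cube = cc.build_water_cube(200.0, spacing=5.0)
        g = cube.grid
        r = np.linalg.norm(g.voxel_centers(), axis=-1)
        tvals = np.where(r < 20.0, 1.0, 0.0)
        tg = TermaGrid(
            Grid3D(g.spacing, g.origin, tvals),
            np.full(g.dims, 2.0),
            np.zeros(g.dims),
            np.zeros(g.dims),
            BeamGeometry(0.0),
        )
        from ccdose.kernels import analytic_point_kernel

        cck = build_cck(analytic_point_kernel(2.0))
        dose = superpose(tg, cube, cck, make_cone_set(), tilt=False)
        ratio = float((dose.values * cube.ed).sum() / (tvals * cube.ed).sum())
        assert ratio == pytest.approx(1.0, abs=0.01)

    def test_misaligned_grids_rejected(self):
        vol, tg, _ = point_terma(n=21)
        other = cc.build_water_cube(100.0, spacing=10.0)
        cck, cones = forward_exponential_cck()
        with pytest.raises(ValueError, match="aligned"):
            superpose(tg, other, cck, cones)


class TestPlanDose:
    def test_dose_linear_in_mu_and_segment_splitting(self, beam6):
        """Two identical 50 MU segments equal one 100 MU segment exactly,
        and dose is proportional to MU."""
        cube = cc.build_water_cube(100.0, spacing=10.0)
        cfg = cc.EngineConfig(fluence_spacing_mm=2.0)
        one = cc.build_square_field_plan(5.0, mu=100.0)
        two = cc.build_square_field_plan(5.0, mu=50.0)
        two.beams.append(two.beams[0])
        d_one = cc.calc_plan_dose(one, cube, beam6, cfg).dose.values
        d_two = cc.calc_plan_dose(two, cube, beam6, cfg).dose.values
        np.testing.assert_allclose(d_two, d_one, rtol=1e-9)

        half = cc.calc_plan_dose(
            cc.build_square_field_plan(5.0, mu=50.0), cube, beam6, cfg
        ).dose.values
        np.testing.assert_allclose(2.0 * half, d_one, rtol=1e-9)

    def test_parallel_opposed_beams_symmetric_about_midplane(self, beam6):
        cube = cc.build_water_cube(150.0, spacing=5.0)
        plan = cc.Plan(
            [
                cc.PlanBeam([cc.ControlPoint(0.0, 50.0, a)])
                for a in [cc.build_square_field_plan(5.0).beams[0].control_points[0].aperture] * 2
            ]
        )
        plan.beams[1].control_points[0].gantry_deg = 180.0
        cfg = cc.EngineConfig(fluence_spacing_mm=2.0)
        X = cube.grid.voxel_centers()
        mask = (np.abs(X[..., 0]) <= 15) & (np.abs(X[..., 1]) <= 15)
        dose = cc.calc_plan_dose(plan, cube, beam6, cfg, mask=mask).dose.values
        asym = np.abs(dose - dose[:, :, ::-1]) / dose.max()
        assert asym[mask].max() < 0.005

    def test_dose_nonnegative_everywhere(self, slab_runs_15mv):
        assert np.all(slab_runs_15mv["plain"].values >= 0)

    def test_empty_plan_warns_and_returns_zero(self, beam6):
        cube = cc.build_water_cube(100.0, spacing=10.0)
        with pytest.warns(UserWarning, match="empty plan"):
            res = cc.calc_plan_dose(cc.Plan([]), cube, beam6)
        assert res.dose.values.max() == 0.0


class TestWaterPDD:
    def test_buildup_then_monotone_falloff(self, water_pdds):
        for name, pdd in water_pdds.items():
            assert pdd.d_max > 5.0  # genuine build-up region
            beyond = pdd.values[pdd.depths > pdd.d_max + 10.0]
            rises = np.diff(beyond) > 0.2  # no local maxima beyond 0.2%
            assert not np.any(rises), name

    def test_dmax_increases_with_nominal_energy(self, water_pdds):
        d6 = water_pdds["6MV"].d_max
        d10 = water_pdds["10FFF"].d_max
        d15 = water_pdds["15MV"].d_max
        assert d6 < d15
        assert d6 <= d10 <= d15

    def test_cone_refinement_changes_pdd_less_than_one_percent(self, beam6):
        """Doubling the cone discretization (8x6 -> 16x12) leaves the
        water PDD beyond build-up unchanged to < 1%."""
        import ccdose.fixtures as fx

        g = fx._make_grid(
            np.array([120.0, 120.0, 200.0]), np.array([5.0, 5.0, 2.5]), (0, 0, -100.0)
        )
        g.values[:] = 1.0
        vol = DensityVolume(g, np.ones(g.dims, dtype=bool))
        plan = cc.build_square_field_plan(8.0, mu=1.0)
        fine_edges = np.array(
            [0, 3, 6, 9, 12, 16, 20, 25, 30, 37, 45, 57, 70, 90, 110, 145, 180.0]
        )
        curves = []
        for cones in (make_cone_set(), make_cone_set(fine_edges, 12)):
            res = cc.calc_plan_dose(plan, vol, beam6, cc.EngineConfig(cones=cones))
            curves.append(
                cc.extract_pdd(res.dose, (0, 0, 0), (0, 0, -1), normalization_depth=50.0)
            )
        a, b = curves
        sel = (a.depths > 40) & (a.depths < 190)
        diff = np.abs(a.values[sel] - np.interp(a.depths[sel], b.depths, b.values))
        assert diff.max() < 1.0


class TestArcOrchestration:
    def test_arc_terma_and_superposition_counts(self, beam6):
        cube = cc.build_water_cube(100.0, spacing=10.0)
        plan = cc.build_arc_plan(2.0, total_mu=100.0)
        cfg = cc.EngineConfig(fluence_spacing_mm=2.0)
        res = cc.calc_plan_dose(plan, cube, beam6, cfg)
        assert res.report.n_terma_evaluations == 180
        assert res.report.n_superposition_evaluations == 72
        assert res.report.mu_delivered == pytest.approx(100.0, rel=1e-12)
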