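"""Shared fixtures.  Engine runs are kept at coarse grid spacings (5 mm
laterally, 2.5 mm along depth where build-up matters) so the whole suite
stays fast; the physics being checked is resolution-robust at these scales.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import ccdose as cc
import ccdose.fixtures as fx

settings.register_profile("ci", derandomize=True, max_examples=30, deadline=None, database=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def materials():
    return cc.default_materials()


@pytest.fixture(scope="session")
def engine_config():
    return cc.EngineConfig()


@pytest.fixture(scope="session")
def beam6():
    b = cc.load_beam_model("6MV")
    b.calibration_scale = 1.0  # relative mode for physics checks
    return b


@pytest.fixture(scope="session")
def beam15():
    b = cc.load_beam_model("15MV")
    b.calibration_scale = 1.0
    return b


@pytest.fixture(scope="session")
def calibrated_beam6(engine_config):
    b = cc.load_beam_model("6MV")
    cc.calibrate_output(b, engine_config, grid_spacing=5.0)
    return b


def _tall_water(spacing_lat=5.0, spacing_z=2.5, lateral=120.0, depth=200.0):
    g = fx._make_grid(
        np.array([lateral, lateral, depth]),
        np.array([spacing_lat, spacing_lat, spacing_z]),
        (0.0, 0.0, -depth / 2.0),
    )
    g.values[:] = 1.0
    return cc.DensityVolume(g, np.ones(g.dims, dtype=bool))


@pytest.fixture(scope="session")
def water_pdds():
    """Central-axis PDDs of an 8x8 cm^2 field for the three surrogate energies."""
    vol = _tall_water()
    plan = cc.build_square_field_plan(8.0, mu=1.0)
    cfg = cc.EngineConfig()
    out = {}
    for name in ("6MV", "10FFF", "15MV"):
        b = cc.load_beam_model(name)
        b.calibration_scale = 1.0
        res = cc.calc_plan_dose(plan, vol, b, cfg)
        out[name] = cc.extract_pdd(res.dose, (0, 0, 0), (0, 0, -1))
    return out


@pytest.fixture(scope="session")
def slab_runs_15mv(beam15):
    """2x2 cm^2 15 MV-surrogate field on the lung slab phantom, with and
    without the HCS density filter; dose restricted to a near-axis block."""
    slab = cc.build_slab_phantom(spacing=np.array([5.0, 5.0, 2.5]), lateral_mm=200.0)
    plan = cc.build_square_field_plan(2.0, mu=1.0)
    X = slab.grid.voxel_centers()
    mask = (np.abs(X[..., 0]) <= 40) & (np.abs(X[..., 1]) <= 40)
    plain = cc.calc_plan_dose(plan, slab, beam15, cc.EngineConfig(), mask=mask).dose
    hcs = cc.calc_plan_dose(
        plan, slab, beam15, cc.EngineConfig(hcs=cc.HCSParams()), mask=mask
    ).dose
    return {"density": slab, "mask": mask, "plain": plain, "hcs": hcs, "centers": X}


def make_gamma_pair(seed: int, dims=(20, 20, 20), spacing=2.5):
    """Smooth correlated random reference/evaluated dose pair."""
    from scipy.ndimage import gaussian_filter

    from ccdose.core_model import Grid3D

    rng = np.random.default_rng(seed)
    base = gaussian_filter(rng.random(dims), 2.0)
    noise = gaussian_filter(rng.standard_normal(dims), 1.5)
    ref = Grid3D([spacing] * 3, [0.0, 0.0, 0.0], base * 2.0 + 0.2)
    ev = Grid3D([spacing] * 3, [0.0, 0.0, 0.0], (base + 0.02 * noise) * 2.0 + 0.2)
    return ref, ev
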