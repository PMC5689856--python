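"""Polyenergetic TERMA: transporting fluence through the density volume.

For each voxel and each of the 16 spectrum bins,

    T += Psi_bin * (mu/rho)_material(ED),bin * E_bin
         * exp(-(mu/rho)_water,bin * d_we) * (SAD / r)^2

where ``d_we`` is the water-equivalent (ED-weighted) radiological path from
the source to the voxel and ``r`` the source distance.  Bin-wise attenuation
of the 16-bin spectrum is the beam-hardening mechanism; the per-voxel mean
energy of the interacting photons is recorded for hardening-aware kernel
selection downstream.

Transport vs release split: the attenuation path uses *water* mass
attenuation with the ED-weighted path length (effective-pathlength
heterogeneity correction), while the local energy-release factor uses the
blended material's own mass attenuation coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _tracing
from .beam_model import BeamGeometry, BeamModel, FluenceMap
from .core_model import DensityVolume, Grid3D, MaterialTable, default_materials

__all__ = ["TermaGrid", "radiological_path", "compute_terma", "terma_for_arc"]


@dataclass
class TermaGrid:
    """TERMA and companion per-voxel fields on the calculation grid."""

    grid: Grid3D  # TERMA per voxel (engine units per MU before calibration)
    mean_energy: np.ndarray  # MeV, release-weighted mean photon energy
    rad_depth: np.ndarray  # mm water-equivalent source->voxel path
    contamination: np.ndarray  # electron-contamination surface dose term
    geometry: BeamGeometry
    mu: float = 0.0

    def __post_init__(self) -> None:
        if np.any(self.grid.values < 0):
            raise ValueError("TERMA must be >= 0")


def radiological_path(density: DensityVolume, src, dst) -> float:
    """Water-equivalent path length (mm) from src to dst through the volume.

    Exact voxel-traversal line integral of relative electron density
    (Siddon-style); portions of the segment outside the grid contribute 0.
    A zero-length ray returns 0.
    """
    g = density.grid
    return float(
        _tracing.ray_path_ed(
            g.values,
            g.spacing,
            g.origin,
            np.asarray(src, dtype=float),
            np.asarray(dst, dtype=float),
        )
    )


def _voxel_rad_depths(density: DensityVolume, positions: np.ndarray, geometry: BeamGeometry) -> np.ndarray:
    g = density.grid
    if geometry.parallel:
        # start each ray well outside the grid, upstream along the beam axis
        lo, hi = g.bounds()
        reach = float(np.linalg.norm(hi - lo)) + 10.0
        p0 = positions - geometry.direction * reach
    else:
        p0 = np.broadcast_to(geometry.source, positions.shape).copy()
    return _tracing.ray_paths_ed(
        g.values, g.spacing, g.origin, np.ascontiguousarray(p0), np.ascontiguousarray(positions)
    )


def compute_terma(
    fluence: FluenceMap,
    density: DensityVolume,
    beam: BeamModel,
    materials: MaterialTable | None = None,
    mask: np.ndarray | None = None,
    attenuation: bool = True,
    spectrum_override=None,
) -> TermaGrid:
    """Polyenergetic TERMA for one fluence map.

    ``mask`` restricts the computed voxels (default: the body mask);
    ``attenuation=False`` disables the exponential term (used by the
    inverse-square verification); ``spectrum_override`` replaces the model's
    bin energies/weights with caller-supplied ``(energies, mu_water_per_mm)``
    for monoenergetic closed-form tests while reusing the fluence map shape.
    """
    if materials is None:
        materials = default_materials()
    g = density.grid
    geometry = fluence.geometry
    if mask is None:
        mask = density.body_mask
    idx = np.argwhere(mask)
    positions = g.origin + idx * g.spacing

    d_we = _voxel_rad_depths(density, positions, geometry)
    u, v, t_axis = geometry.plane_coords(positions)

    psi = fluence.sample_bins(u, v)  # (n, 16)
    energies = materials.bin_energies
    # water mass attenuation in 1/mm at unit ED: (mu/rho)[cm^2/g] * 1 g/cm^3 / 10
    mu_water_mm = materials.water.mu_over_rho / 10.0
    if spectrum_override is not None:
        energies, mu_water_mm = spectrum_override
        energies = np.asarray(energies, dtype=float)
        mu_water_mm = np.asarray(mu_water_mm, dtype=float)

    if attenuation:
        atten = np.exp(-np.outer(d_we, mu_water_mm))
    else:
        atten = np.ones((len(d_we), len(energies)))

    if geometry.parallel:
        invsq = np.ones(len(d_we))
    else:
        invsq = (geometry.sad / t_axis) ** 2

    ed_vox = g.values[mask]
    mu_mat, _ = materials.blend(ed_vox)  # (n, 16), cm^2/g
    release = psi * atten * mu_mat * energies  # per-bin released energy
    terma_vals = release.sum(axis=1) * invsq

    # mean energy of interacting photons (interaction-rate weighted)
    rate = psi * atten * mu_mat
    rate_sum = rate.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_e = np.where(rate_sum > 0, (rate * energies).sum(axis=1) / rate_sum, 0.0)

    # contamination: surface term proportional to the open-field energy
    # fluence scale, decaying exponentially with water-equivalent depth
    cont_fluence = fluence.sample_contamination(u, v)
    cont_scale = float(np.sum(beam.primary_spectrum.bin_weights * energies * mu_water_mm * 10.0)) \
        if spectrum_override is None else float(np.sum(energies * mu_water_mm * 10.0))
    cont = cont_fluence * cont_scale * np.exp(-d_we / beam.contamination_depth_constant) * invsq

    tg = np.zeros(g.dims)
    me = np.zeros(g.dims)
    rd = np.zeros(g.dims)
    cg = np.zeros(g.dims)
    sel = tuple(idx.T)
    tg[sel] = terma_vals
    me[sel] = mean_e
    rd[sel] = d_we
    cg[sel] = cont
    return TermaGrid(
        Grid3D(g.spacing, g.origin, tg, unit="TERMA/MU"),
        me,
        rd,
        cg,
        geometry,
        mu=fluence.mu,
    )


def terma_for_arc(
    plan_beam,
    density: DensityVolume,
    beam: BeamModel,
    materials: MaterialTable | None = None,
    arc_terma_deg: float = 2.0,
    mask: np.ndarray | None = None,
    plane_spacing: float = 1.0,
) -> list[TermaGrid]:
    """TERMA evaluated across an arc at fixed angular resolution.

    The arc is split into sectors of ``arc_terma_deg``; each sector's MU is
    interpolated from the control-point cumulative MU and its TERMA is
    evaluated at the sector midpoint gantry angle with the aperture of the
    nearest control point.  A static (single-CP) beam degenerates to one
    TERMA evaluation.  Sector MUs sum exactly to the beam MU.
    """
    from .beam_model import compute_fluence

    cps = plan_beam.control_points
    if len(cps) == 1:
        cp = cps[0]
        geom = BeamGeometry(cp.gantry_deg, sad=beam.sad)
        fl = compute_fluence(beam, cp.aperture, cp.mu, geom, plane_spacing=plane_spacing)
        return [compute_terma(fl, density, beam, materials, mask=mask)]

    angles, cum = plan_beam.cumulative_mu()
    start, stop = angles[0], angles[-1]
    n_sectors = int(round((stop - start) / arc_terma_deg))
    edges = start + arc_terma_deg * np.arange(n_sectors + 1)
    sector_mu = np.interp(edges[1:], angles, cum) - np.interp(edges[:-1], angles, cum)
    mids = (edges[:-1] + edges[1:]) / 2.0

    out = []
    for mid, mu in zip(mids, sector_mu):
        nearest = int(np.argmin(np.abs(angles - mid)))
        geom = BeamGeometry(mid % 360.0, sad=beam.sad)
        fl = compute_fluence(beam, cps[nearest].aperture, mu, geom, plane_spacing=plane_spacing)
        out.append(compute_terma(fl, density, beam, materials, mask=mask))
    return out
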