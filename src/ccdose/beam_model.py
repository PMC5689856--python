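"""Treatment-head model: sources, collimation, and fluence maps.

The head is modeled with three sources, each configured per nominal energy:

* a **primary** point source with its own 16-bin spectrum and an arbitrary
  sampled radial intensity profile (non-flat for flattening-filter-free
  beams);
* an **extrafocal** (head-scatter) Gaussian plane source below the focal
  spot with a softer spectrum — its contribution is the open-aperture
  primary fluence convolved with the projected source visibility, so it
  spills beyond the geometric field edge and is partially obscured for
  small apertures;
* an **electron contamination** source handled as a separate fluence
  channel that deposits as a surface term with exponential depth falloff.

Jaws and MLC are modeled explicitly: rounded leaf ends attenuate by the
chord length through a circle of the configured leaf-end radius, and a
tongue-and-groove strip along each leaf-side edge takes the more-blocking
of the two adjacent rows' transmissions.

Surrogate beam models for 6 MV, 10 MV FFF and 15 MV ship with the package
(:func:`load_beam_model`); vendor spectra and profiles are proprietary, so
these are self-authored stand-ins with the documented structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import yaml
from scipy.ndimage import gaussian_filter

from .core_model import ConfigurationError, Spectrum

__all__ = [
    "Aperture",
    "BeamGeometry",
    "BeamModel",
    "FluenceMap",
    "MLCParams",
    "aperture_transmission",
    "compute_fluence",
    "calibrate_output",
    "load_beam_model",
]


# ---------------------------------------------------------------------------
# Collimation


@dataclass
class MLCParams:
    leaf_widths: np.ndarray  # mm at isocenter, one per leaf row
    transmission: float = 0.015
    leaf_end_radius: float = 80.0  # mm
    leaf_height: float = 70.0  # mm along beam
    tongue_groove_width: float = 1.0  # mm

    def __post_init__(self) -> None:
        self.leaf_widths = np.asarray(self.leaf_widths, dtype=float)
        if np.any(self.leaf_widths <= 0):
            raise ConfigurationError("leaf widths must be > 0")
        if not 0 < self.transmission < 1:
            raise ConfigurationError("MLC transmission must be in (0, 1)")

    @property
    def row_edges(self) -> np.ndarray:
        """Leaf-row boundaries in v (mm at isocenter), bank centered on v=0."""
        edges = np.concatenate([[0.0], np.cumsum(self.leaf_widths)])
        return edges - edges[-1] / 2.0

    @property
    def mu_leaf(self) -> float:
        """Effective linear attenuation of leaf material (per mm)."""
        return -math.log(self.transmission) / self.leaf_height


@dataclass
class Aperture:
    """Jaw and MLC shape, all positions in mm projected to the isocenter plane."""

    jaw_x: tuple[float, float]
    jaw_y: tuple[float, float]
    leaf_pairs: list[tuple[float, float]] | None = None  # (left_tip, right_tip) per row

    def __post_init__(self) -> None:
        if self.jaw_x[0] > self.jaw_x[1] or self.jaw_y[0] > self.jaw_y[1]:
            raise ConfigurationError("jaw positions must satisfy x1 <= x2, y1 <= y2")
        if self.leaf_pairs is not None:
            for left, right in self.leaf_pairs:
                if left > right:
                    raise ConfigurationError("leaf pair must satisfy left <= right")


def _leaf_end_thickness(depth_into_leaf: np.ndarray, mlc: MLCParams) -> np.ndarray:
    """Chord length (mm) through the rounded leaf end vs depth past the tip.

    The leaf end is a cylinder of radius ``leaf_end_radius`` tangent to the
    nominal tip; a ray at depth ``x`` past the tip traverses the vertical
    chord 2*sqrt(r^2 - (r - x)^2) capped at the full leaf height.
    """
    r = mlc.leaf_end_radius
    h = mlc.leaf_height
    s = r - np.asarray(depth_into_leaf, dtype=float)  # distance from circle center
    chord = np.zeros_like(s)
    inside = s < r
    chord[inside] = 2.0 * np.sqrt(np.maximum(r * r - s[inside] ** 2, 0.0))
    chord[s <= 0] = h
    return np.minimum(chord, h)


def _row_transmission(u: np.ndarray, left: float, right: float, mlc: MLCParams) -> np.ndarray:
    """Transmission profile across one leaf row as a function of u (mm)."""
    t_left = _leaf_end_thickness(left - u, mlc)  # material where u < left
    t_right = _leaf_end_thickness(u - right, mlc)
    return np.exp(-mlc.mu_leaf * np.minimum(t_left + t_right, mlc.leaf_height))


def _transmission_map(
    u: np.ndarray,
    v: np.ndarray,
    aperture: Aperture,
    mlc: MLCParams,
    jaw_transmission: float,
) -> np.ndarray:
    """Combined jaw+MLC transmission on the (u, v) isocenter-plane lattice."""
    in_x = (u >= aperture.jaw_x[0]) & (u <= aperture.jaw_x[1])
    in_y = (v >= aperture.jaw_y[0]) & (v <= aperture.jaw_y[1])
    jaw = np.where(np.outer(in_x, in_y), 1.0, jaw_transmission)

    if aperture.leaf_pairs is None:
        return jaw

    edges = mlc.row_edges
    if len(aperture.leaf_pairs) != len(edges) - 1:
        raise ConfigurationError("leaf_pairs length must match the MLC leaf count")
    # per-row profiles, then assemble over v
    profiles = np.stack(
        [_row_transmission(u, lt, rt, mlc) for lt, rt in aperture.leaf_pairs]
    )  # (n_rows, nu)
    row_idx = np.clip(np.searchsorted(edges, v, side="right") - 1, 0, len(profiles) - 1)
    mlc_map = profiles[row_idx, :].T  # (nu, nv)
    # outside the leaf bank the MLC does not cover the field
    outside_bank = (v < edges[0]) | (v > edges[-1])
    mlc_map[:, outside_bank] = 1.0

    # tongue-and-groove strips along interior row boundaries: the strip takes
    # the more-blocking of the two adjacent rows' local transmissions
    tg = mlc.tongue_groove_width
    if tg > 0:
        for b in range(1, len(profiles)):
            strip = np.abs(v - edges[b]) < tg / 2.0
            if np.any(strip):
                worst = np.minimum(profiles[b - 1], profiles[b])
                mlc_map[:, strip] = worst[:, None]
    return jaw * mlc_map


def aperture_transmission(
    point_iso: tuple[float, float],
    aperture: Aperture,
    mlc: MLCParams,
    jaw_transmission: float = 0.002,
) -> float:
    """Combined jaw/MLC transmission at a single isocenter-plane point (u, v)."""
    u = np.array([point_iso[0]], dtype=float)
    v = np.array([point_iso[1]], dtype=float)
    return float(_transmission_map(u, v, aperture, mlc, jaw_transmission)[0, 0])


# ---------------------------------------------------------------------------
# Beam model


@dataclass
class BeamModel:
    name: str
    primary_spectrum: Spectrum
    extrafocal_spectrum: Spectrum
    primary_radial_profile: np.ndarray  # (n, 2): radius mm, relative intensity
    extrafocal_fraction: float
    extrafocal_source_width: float  # mm, Gaussian sigma at the source plane
    extrafocal_distance: float  # mm below the focal spot
    contamination_amplitude: float
    contamination_depth_constant: float  # mm
    sad: float
    dose_per_mu: float  # Gy/MU at reference conditions
    ref_field_cm: float
    ref_depth_mm: float
    ref_ssd_mm: float
    mlc: MLCParams
    jaw_transmission: float = 0.002
    calibration_scale: float | None = None  # set by calibrate_output

    def __post_init__(self) -> None:
        if self.sad <= 0:
            raise ConfigurationError("SAD must be > 0")
        for f in (self.extrafocal_fraction, self.jaw_transmission):
            if not 0 <= f <= 1:
                raise ConfigurationError("fractions must lie in [0, 1]")
        self.primary_radial_profile = np.asarray(self.primary_radial_profile, dtype=float)

    def radial_intensity(self, r_mm: np.ndarray) -> np.ndarray:
        tab = self.primary_radial_profile
        return np.interp(r_mm, tab[:, 0], tab[:, 1])

    @property
    def extrafocal_sigma_iso(self) -> float:
        """Extrafocal Gaussian sigma projected to the isocenter plane (mm)."""
        d = self.extrafocal_distance
        return self.extrafocal_source_width * max(self.sad - d, 0.0) / d


def load_beam_model(name_or_path: str | Path) -> BeamModel:
    """Load a beam model config; ``"6MV"``, ``"10FFF"``, ``"15MV"`` name the
    packaged surrogate models, anything else is taken as a YAML path."""
    key = str(name_or_path).lower().replace(" ", "")
    packaged = {"6mv": "beam_6mv.yaml", "10fff": "beam_10fff.yaml",
                "10mvfff": "beam_10fff.yaml", "15mv": "beam_15mv.yaml"}
    if key in packaged:
        with resources.files("ccdose.data").joinpath(packaged[key]).open() as fh:
            doc = yaml.safe_load(fh)
    else:
        with open(name_or_path) as fh:
            doc = yaml.safe_load(fh)
    prof = doc["primary_radial_profile"]
    return BeamModel(
        name=doc["name"],
        primary_spectrum=Spectrum(
            doc["primary_spectrum"]["bin_energies_mev"],
            doc["primary_spectrum"]["bin_weights"],
        ),
        extrafocal_spectrum=Spectrum(
            doc["extrafocal_spectrum"]["bin_energies_mev"],
            doc["extrafocal_spectrum"]["bin_weights"],
        ),
        primary_radial_profile=np.column_stack([prof["radius_mm"], prof["intensity"]]),
        extrafocal_fraction=float(doc["extrafocal_fraction"]),
        extrafocal_source_width=float(doc["extrafocal_source_width_mm"]),
        extrafocal_distance=float(doc["extrafocal_distance_mm"]),
        contamination_amplitude=float(doc["contamination"]["amplitude"]),
        contamination_depth_constant=float(doc["contamination"]["depth_constant_mm"]),
        sad=float(doc["sad_mm"]),
        dose_per_mu=float(doc["calibration"]["dose_per_mu_gy"]),
        ref_field_cm=float(doc["calibration"]["ref_field_cm"]),
        ref_depth_mm=float(doc["calibration"]["ref_depth_mm"]),
        ref_ssd_mm=float(doc["calibration"]["ref_ssd_mm"]),
        mlc=MLCParams(
            leaf_widths=doc["mlc"]["leaf_widths_mm"],
            transmission=float(doc["mlc"]["transmission"]),
            leaf_end_radius=float(doc["mlc"]["leaf_end_radius_mm"]),
            leaf_height=float(doc["mlc"]["leaf_height_mm"]),
            tongue_groove_width=float(doc["mlc"]["tongue_groove_width_mm"]),
        ),
        jaw_transmission=float(doc["jaw_transmission"]),
    )


# ---------------------------------------------------------------------------
# Beam geometry


@dataclass
class BeamGeometry:
    """Source position and in-plane basis for one gantry angle.

    Gantry 0 has the source at (0, 0, +SAD) with the beam along -z; the
    gantry rotates about +y.  ``parallel=True`` removes divergence (and the
    inverse-square factor) — used by the density-scaling and analytic tests.
    """

    gantry_deg: float
    sad: float = 1000.0
    parallel: bool = False

    @property
    def direction(self) -> np.ndarray:
        g = math.radians(self.gantry_deg)
        return np.array([-math.sin(g), 0.0, -math.cos(g)])

    @property
    def source(self) -> np.ndarray:
        return -self.direction * self.sad

    @property
    def e_u(self) -> np.ndarray:
        g = math.radians(self.gantry_deg)
        return np.array([math.cos(g), 0.0, -math.sin(g)])

    @property
    def e_v(self) -> np.ndarray:
        return np.array([0.0, 1.0, 0.0])

    def plane_coords(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(u, v, depth_along_axis) for mm positions; u, v at isocenter scale."""
        p = np.atleast_2d(points)
        if self.parallel:
            u = p @ self.e_u
            v = p @ self.e_v
            t = p @ self.direction + self.sad  # distance from the virtual source plane
            return u, v, t
        q = p - self.source
        t = q @ self.direction
        scale = self.sad / np.where(t != 0, t, np.inf)
        return (q @ self.e_u) * scale, (q @ self.e_v) * scale, t


# ---------------------------------------------------------------------------
# Fluence


@dataclass
class FluenceMap:
    """Energy-differential fluence on the isocenter plane.

    ``values`` has shape (nu, nv, 16): photon fluence density per mm^2 at
    isocenter scale, MU-weighted, including primary and extrafocal channels.
    ``contamination`` is the separate electron-contamination channel.
    """

    u: np.ndarray  # (nu,) mm
    v: np.ndarray  # (nv,) mm
    values: np.ndarray  # (nu, nv, 16)
    contamination: np.ndarray  # (nu, nv)
    geometry: BeamGeometry
    mu: float

    def __post_init__(self) -> None:
        if self.values.shape[-1] != 16:
            raise ConfigurationError("fluence needs 16 photon bins")
        if np.any(self.values < 0) or np.any(self.contamination < 0):
            raise ValueError("fluence must be non-negative")

    def sample_bins(self, u_q: np.ndarray, v_q: np.ndarray) -> np.ndarray:
        """Bilinear sample of all 16 bins at query points -> (n, 16)."""
        return _bilinear_stack(self.u, self.v, self.values, u_q, v_q)

    def sample_contamination(self, u_q: np.ndarray, v_q: np.ndarray) -> np.ndarray:
        return _bilinear_stack(self.u, self.v, self.contamination[..., None], u_q, v_q)[:, 0]


def _bilinear_stack(u, v, arr, uq, vq):
    nu, nv = arr.shape[:2]
    fu = np.clip((uq - u[0]) / (u[1] - u[0]), 0, nu - 1)
    fv = np.clip((vq - v[0]) / (v[1] - v[0]), 0, nv - 1)
    i0 = np.clip(np.floor(fu).astype(int), 0, nu - 2)
    j0 = np.clip(np.floor(fv).astype(int), 0, nv - 2)
    du = (fu - i0)[:, None]
    dv = (fv - j0)[:, None]
    a = arr[i0, j0] * (1 - du) * (1 - dv)
    a += arr[i0 + 1, j0] * du * (1 - dv)
    a += arr[i0, j0 + 1] * (1 - du) * dv
    a += arr[i0 + 1, j0 + 1] * du * dv
    return a


def compute_fluence(
    beam: BeamModel,
    aperture: Aperture,
    segment_mu: float,
    geometry: BeamGeometry | None = None,
    plane_spacing: float = 1.0,
    plane_margin: float = 40.0,
) -> FluenceMap:
    """Energy-differential fluence entering the patient for one segment.

    The primary channel is ``mu * radial_profile(r) * transmission(u, v)``
    per spectrum bin.  The extrafocal channel convolves the in-aperture
    primary with the projected finite-source Gaussian, scaled by the
    extrafocal fraction, so it is reduced for apertures that partially
    obscure the distributed source.  The contamination channel is a broadly
    blurred copy of the aperture, carried separately.
    """
    if geometry is None:
        geometry = BeamGeometry(0.0, sad=beam.sad)
    lo_u = aperture.jaw_x[0] - plane_margin
    hi_u = aperture.jaw_x[1] + plane_margin
    lo_v = aperture.jaw_y[0] - plane_margin
    hi_v = aperture.jaw_y[1] + plane_margin
    u = np.arange(lo_u, hi_u + plane_spacing / 2, plane_spacing)
    v = np.arange(lo_v, hi_v + plane_spacing / 2, plane_spacing)

    T = _transmission_map(u, v, aperture, beam.mlc, beam.jaw_transmission)
    r = np.hypot(*np.meshgrid(u, v, indexing="ij"))
    profile = beam.radial_intensity(r)
    open_field = segment_mu * profile

    primary = open_field * T
    sigma_px = beam.extrafocal_sigma_iso / plane_spacing
    extrafocal = beam.extrafocal_fraction * gaussian_filter(primary, sigma_px, mode="nearest")

    w_p = beam.primary_spectrum.bin_weights
    w_e = beam.extrafocal_spectrum.bin_weights
    values = primary[..., None] * w_p + extrafocal[..., None] * w_e

    cont_sigma_px = 30.0 / plane_spacing  # broad electron spread at the surface
    contamination = beam.contamination_amplitude * gaussian_filter(
        segment_mu * T, cont_sigma_px, mode="nearest"
    )
    return FluenceMap(u, v, values, contamination, geometry, segment_mu)


# ---------------------------------------------------------------------------
# Absolute calibration


def calibrate_output(beam: BeamModel, config=None, grid_spacing: float = 5.0) -> float:
    """Run the engine once at reference conditions and set the absolute scale.

    Reference geometry: an open ``ref_field_cm`` square field on a water cube
    whose surface sits at the reference SSD, with the reference point at the
    isocenter (depth ``ref_depth_mm``).  The returned scale makes the engine
    dose at that point equal ``dose_per_mu``; it is stored on the model.
    Recalibrating is idempotent (the recomputed scale is unchanged).
    """
    from .fixtures import build_water_cube, build_square_field_plan
    from .superposition import EngineConfig, calc_plan_dose

    if config is None:
        config = EngineConfig()
    side = 200.0
    # cube center so that the beam-entry surface (facing +z) is at depth 0
    center_z = beam.ref_depth_mm - side / 2.0
    phantom = build_water_cube(side_mm=side, spacing=grid_spacing, center=(0, 0, center_z))
    plan = build_square_field_plan(beam.ref_field_cm, beam.name, mu=1.0)

    previous = beam.calibration_scale
    beam.calibration_scale = 1.0
    result = calc_plan_dose(plan, phantom, beam, config)
    d0 = float(result.dose.sample(np.zeros(3)))
    if d0 <= 0:
        beam.calibration_scale = previous
        raise RuntimeError("calibration produced zero dose at the reference point")
    beam.calibration_scale = beam.dose_per_mu / d0
    return beam.calibration_scale
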