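"""Synthetic phantoms, plans, and plan serialization.

Everything the validation protocol needs is generated here at run time —
water cube, lung slab phantom, anthropomorphic-style thorax phantom, open
and MLC-shaped square fields, a five-beam coplanar lung plan, and full
arcs — so no external data is required.  All builders are deterministic.

Geometry reminders (see :mod:`ccdose.core_model`): isocenter at the origin,
gantry 0 beam travels along -z.  The slab phantom places its entry surface
at z = 0 with slabs stacked along -z; the water cube and thorax phantom are
centered on the isocenter unless told otherwise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .beam_model import Aperture
from .core_model import DensityVolume, Grid3D, Structure, StructureSet

__all__ = [
    "ControlPoint",
    "PlanBeam",
    "Plan",
    "build_water_cube",
    "build_slab_phantom",
    "build_thorax_phantom",
    "build_square_field_plan",
    "build_five_beam_lung_plan",
    "build_arc_plan",
    "load_plan",
    "save_plan",
]

# MLC bank used by the plan builders: 40 leaf rows x 10 mm (matches the
# packaged surrogate beam models).
_LEAF_WIDTHS = np.full(40, 10.0)
_ROW_EDGES = np.concatenate([[0.0], np.cumsum(_LEAF_WIDTHS)]) - 200.0
_RETRACTED = None


# ---------------------------------------------------------------------------
# Plans


@dataclass
class ControlPoint:
    """One plan control point.

    ``mu`` is the MU delivered since the previous control point (0 for the
    first CP of an arc); for a static segment beam each CP is a segment and
    carries the full segment MU.
    """

    gantry_deg: float
    mu: float
    aperture: Aperture


@dataclass
class PlanBeam:
    control_points: list[ControlPoint]
    name: str = "beam"

    @property
    def is_arc(self) -> bool:
        return len(self.control_points) > 1

    @property
    def total_mu(self) -> float:
        return float(sum(cp.mu for cp in self.control_points))

    def cumulative_mu(self) -> tuple[np.ndarray, np.ndarray]:
        """(gantry angles, cumulative MU) for MU-vs-angle interpolation."""
        ang = np.array([cp.gantry_deg for cp in self.control_points])
        cum = np.cumsum([cp.mu for cp in self.control_points])
        return ang, cum


@dataclass
class Plan:
    beams: list[PlanBeam]
    energy_label: str = "6MV"

    @property
    def total_mu(self) -> float:
        return float(sum(b.total_mu for b in self.beams))


def save_plan(plan: Plan, path: str | Path) -> None:
    """Serialize a plan to the documented JSON dialect (mm at isocenter, IEC-style gantry degrees)."""
    doc = {
        "energy": plan.energy_label,
        "beams": [
            {
                "name": b.name,
                "control_points": [
                    {
                        "gantry_deg": cp.gantry_deg,
                        "mu": cp.mu,
                        "jaw_x": list(cp.aperture.jaw_x),
                        "jaw_y": list(cp.aperture.jaw_y),
                        "leaf_pairs": (
                            None
                            if cp.aperture.leaf_pairs is None
                            else [list(p) for p in cp.aperture.leaf_pairs]
                        ),
                    }
                    for cp in b.control_points
                ],
            }
            for b in plan.beams
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_plan(path: str | Path) -> Plan:
    doc = json.loads(Path(path).read_text())
    beams = []
    for b in doc["beams"]:
        cps = [
            ControlPoint(
                gantry_deg=float(cp["gantry_deg"]),
                mu=float(cp["mu"]),
                aperture=Aperture(
                    jaw_x=tuple(cp["jaw_x"]),
                    jaw_y=tuple(cp["jaw_y"]),
                    leaf_pairs=(
                        None
                        if cp.get("leaf_pairs") is None
                        else [tuple(p) for p in cp["leaf_pairs"]]
                    ),
                ),
            )
            for cp in b["control_points"]
        ]
        beams.append(PlanBeam(cps, name=b.get("name", "beam")))
    return Plan(beams, energy_label=doc.get("energy", "6MV"))


# ---------------------------------------------------------------------------
# Phantoms


def _make_grid(dims_mm: np.ndarray, spacing, center) -> Grid3D:
    spacing = np.broadcast_to(np.asarray(spacing, dtype=float), (3,)).copy()
    dims = np.maximum(np.round(np.asarray(dims_mm, float) / spacing).astype(int), 1)
    origin = np.asarray(center, float) - (dims - 1) * spacing / 2.0
    return Grid3D(spacing, origin, np.zeros(dims), unit="rel. electron density")


def build_water_cube(
    side_mm: float = 200.0, spacing: float = 2.5, center=(0.0, 0.0, 0.0)
) -> DensityVolume:
    """Homogeneous unit-density cube (default 20x20x20 cm^3), body = cube."""
    if side_mm <= 0:
        raise ValueError("side_mm must be > 0")
    grid = _make_grid(np.full(3, side_mm), spacing, center)
    grid.values[:] = 1.0
    return DensityVolume(grid, np.ones(grid.dims, dtype=bool))


def build_slab_phantom(
    spacing: float = 2.5,
    lateral_mm: float = 300.0,
    layers: tuple[tuple[float, float], ...] = ((50.0, 1.0), (50.0, 0.3), (200.0, 1.0)),
) -> DensityVolume:
    """Wide lung-slab phantom: 5 cm water / 5 cm lung (ED 0.3) / 20 cm water.

    The beam-entry surface is the plane z = 0; depth d corresponds to
    z = -d.  Lateral extent defaults to 300 mm so even a 20 cm field is
    fully covered.
    """
    if np.any(np.asarray(spacing) <= 0):
        raise ValueError("spacing must be > 0")
    total = sum(d for d, _ in layers)
    grid = _make_grid(
        np.array([lateral_mm, lateral_mm, total]), spacing, (0.0, 0.0, -total / 2.0)
    )
    z = grid.axis_coords(2)
    depth = -z
    ed = np.empty_like(depth)
    top = 0.0
    for thickness, density in layers:
        sel = (depth > top) & (depth <= top + thickness)
        ed[sel] = density
        top += thickness
    ed[depth <= 0] = layers[0][1]
    ed[depth > top] = layers[-1][1]
    grid.values[:] = ed[None, None, :]
    return DensityVolume(grid, np.ones(grid.dims, dtype=bool))


def build_thorax_phantom(
    spacing: float = 2.5,
    with_target: bool = True,
    center_on_target: bool = False,
    lung_ed: float = 0.21,
) -> tuple[DensityVolume, StructureSet]:
    """Thorax-like phantom: elliptical body, two lung cylinders, optional target.

    Body: 300 x 300 x 200 mm bounding box, elliptical (x, z) cross-section,
    ED 1.0.  Lungs: cylinders of radius 80 mm along the superior-inferior
    (y) axis at x = +-70 mm, ED ``lung_ed`` (0.21, epoxy-resin-like).
    Target: 40 mm diameter unit-density sphere centered in the right lung.
    ``center_on_target`` shifts the whole phantom so the target center (the
    usual isocenter placement) is at the origin.
    """
    if np.any(np.asarray(spacing) <= 0):
        raise ValueError("spacing must be > 0")
    body_center = np.array([-70.0, 0.0, 0.0]) if center_on_target else np.zeros(3)
    grid = _make_grid(np.array([300.0, 300.0, 200.0]), spacing, body_center)
    pos = grid.voxel_centers() - body_center
    x, y, z = pos[..., 0], pos[..., 1], pos[..., 2]

    body = (x / 150.0) ** 2 + (z / 100.0) ** 2 <= 1.0
    lung_r = ((x - 70.0) ** 2 + z**2 <= 80.0**2) & body
    lung_l = ((x + 70.0) ** 2 + z**2 <= 80.0**2) & body
    target = ((x - 70.0) ** 2 + y**2 + z**2 <= 20.0**2) if with_target else np.zeros_like(body)

    ed = np.where(body, 1.0, 0.0)
    ed[lung_r | lung_l] = lung_ed
    ed[target] = 1.0
    grid.values[:] = ed

    structures = [
        Structure("body", body),
        Structure("lungs", lung_r | lung_l),
    ]
    if with_target:
        structures.append(Structure("target", target))
    return DensityVolume(grid, body), StructureSet(structures)


# ---------------------------------------------------------------------------
# Plan builders


def _closed_leaf_pairs(park_u: float) -> list[tuple[float, float]]:
    return [(park_u, park_u)] * len(_LEAF_WIDTHS)


def build_square_field_plan(
    side_cm: float,
    energy_label: str = "6MV",
    mu: float = 100.0,
    mlc_side_cm: float | None = None,
    gantry_deg: float = 0.0,
) -> Plan:
    """Single static open square field; optionally an MLC-defined square
    aperture inside the jaw opening (leaves outside the opening abut under
    the closed side of the X jaw)."""
    if side_cm <= 0:
        raise ValueError("field side must be > 0")
    half = side_cm * 10.0 / 2.0
    leaf_pairs = _RETRACTED
    if mlc_side_cm is not None:
        mlc_half = mlc_side_cm * 10.0 / 2.0
        park = -(half + 15.0)  # under the X1 jaw
        leaf_pairs = []
        for row in range(len(_LEAF_WIDTHS)):
            v0, v1 = _ROW_EDGES[row], _ROW_EDGES[row + 1]
            overlaps = (v1 > -mlc_half) and (v0 < mlc_half)
            leaf_pairs.append((-mlc_half, mlc_half) if overlaps else (park, park))
    aperture = Aperture(jaw_x=(-half, half), jaw_y=(-half, half), leaf_pairs=leaf_pairs)
    beam = PlanBeam([ControlPoint(gantry_deg, mu, aperture)], name=f"open_{side_cm}x{side_cm}")
    return Plan([beam], energy_label=energy_label)


def build_five_beam_lung_plan(
    energy_label: str = "15MV",
    mu_per_beam: float = 100.0,
    target_radius_mm: float = 20.0,
    margin_mm: float = 7.0,
) -> Plan:
    """Five equally weighted coplanar beams at equispaced gantry angles whose
    MLC apertures conform to the spherical target plus a uniform margin.

    Assumes the isocenter sits at the target center (build the thorax
    phantom with ``center_on_target=True``), so the beam's-eye-view of the
    target is a centered disk at every gantry angle.
    """
    radius = target_radius_mm + margin_mm
    park = -(radius + 25.0)
    leaf_pairs = []
    for row in range(len(_LEAF_WIDTHS)):
        v0, v1 = _ROW_EDGES[row], _ROW_EDGES[row + 1]
        vc = (v0 + v1) / 2.0
        if abs(vc) < radius:
            half_chord = float(np.sqrt(radius**2 - vc**2))
            leaf_pairs.append((-half_chord, half_chord))
        else:
            leaf_pairs.append((park, park))
    aperture = Aperture(
        jaw_x=(-radius - 1.0, radius + 1.0),
        jaw_y=(-radius - 1.0, radius + 1.0),
        leaf_pairs=leaf_pairs,
    )
    beams = [
        PlanBeam([ControlPoint(angle, mu_per_beam, aperture)], name=f"g{int(angle)}")
        for angle in (0.0, 72.0, 144.0, 216.0, 288.0)
    ]
    return Plan(beams, energy_label=energy_label)


def build_arc_plan(
    cp_spacing_deg: float = 2.0,
    total_mu: float = 360.0,
    side_cm: float = 5.0,
    energy_label: str = "6MV",
) -> Plan:
    """Single full 360-degree arc with control points every ``cp_spacing_deg``.

    Control points are inclusive of both 0 and 360 degrees (181 CPs at the
    default 2-degree spacing); MU is split evenly across the inter-CP
    sectors and recorded per CP as MU-since-previous (first CP carries 0).
    """
    if cp_spacing_deg <= 0 or abs(360.0 / cp_spacing_deg - round(360.0 / cp_spacing_deg)) > 1e-9:
        raise ValueError("cp_spacing_deg must divide 360")
    n_sectors = int(round(360.0 / cp_spacing_deg))
    half = side_cm * 10.0 / 2.0
    aperture = Aperture(jaw_x=(-half, half), jaw_y=(-half, half), leaf_pairs=_RETRACTED)
    cps = [ControlPoint(0.0, 0.0, aperture)]
    for k in range(1, n_sectors + 1):
        cps.append(ControlPoint(k * cp_spacing_deg, total_mu / n_sectors, aperture))
    return Plan([PlanBeam(cps, name="arc")], energy_label=energy_label)
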