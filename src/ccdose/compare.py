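"""Dose-comparison instruments: 3D gamma analysis, PDD and profile
extraction, ROI mean dose, surface-layer exclusion, and pass-rate reports.

Gamma definition: for each reference voxel above the low-dose cutoff,

    gamma = min over evaluated positions of
            sqrt( (|dr| / dta)^2 + ((D_eval - D_ref) / delta)^2 )

with ``delta = dose_pct/100 * max(reference)`` under global normalization or
``dose_pct/100 * D_ref`` under local normalization.  The evaluated dose is
trilinearly interpolated; the spatial search uses sub-voxel steps of
``dta/10`` out to a radius of ``3 * dta``.  The routine criteria used
throughout the validation protocol are 3%G/2 mm with a 10% low-dose cutoff
(2%G/2 mm as the tighter companion).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numba as nb
import numpy as np
import pandas as pd

from .core_model import DoseGrid, Grid3D

__all__ = [
    "GammaCriteria",
    "GammaResult",
    "PDDCurve",
    "gamma_analysis",
    "gamma_bruteforce",
    "extract_pdd",
    "roi_mean",
    "surface_exclusion",
    "report",
]


@dataclass
class GammaCriteria:
    dose_pct: float = 3.0
    dta_mm: float = 2.0
    normalization: str = "global"  # or "local"
    low_dose_cutoff_pct: float = 10.0

    def __post_init__(self) -> None:
        if self.dose_pct <= 0 or self.dta_mm <= 0 or self.low_dose_cutoff_pct < 0:
            raise ValueError("gamma criteria must be positive")
        if self.normalization not in ("global", "local"):
            raise ValueError("normalization must be 'global' or 'local'")

    def label(self) -> str:
        n = "G" if self.normalization == "global" else "L"
        return f"{self.dose_pct:g}%{n}/{self.dta_mm:g} mm"


@dataclass
class GammaResult:
    gamma_map: Grid3D  # NaN below cutoff / outside mask
    passing_rate: float  # % of evaluated voxels with gamma <= 1
    n_evaluated: int
    criteria: GammaCriteria


@nb.njit(cache=True, inline="always")
def _trilinear(vals, sp, org, x, y, z):  # pragma: no cover
    fx = (x - org[0]) / sp[0]
    fy = (y - org[1]) / sp[1]
    fz = (z - org[2]) / sp[2]
    nx, ny, nz = vals.shape
    if fx < 0.0 or fy < 0.0 or fz < 0.0 or fx > nx - 1 or fy > ny - 1 or fz > nz - 1:
        return np.nan
    i = min(int(fx), nx - 2) if nx > 1 else 0
    j = min(int(fy), ny - 2) if ny > 1 else 0
    k = min(int(fz), nz - 2) if nz > 1 else 0
    dx = fx - i
    dy = fy - j
    dz = fz - k
    i1 = min(i + 1, nx - 1)
    j1 = min(j + 1, ny - 1)
    k1 = min(k + 1, nz - 1)
    c00 = vals[i, j, k] * (1 - dx) + vals[i1, j, k] * dx
    c10 = vals[i, j1, k] * (1 - dx) + vals[i1, j1, k] * dx
    c01 = vals[i, j, k1] * (1 - dx) + vals[i1, j, k1] * dx
    c11 = vals[i, j1, k1] * (1 - dx) + vals[i1, j1, k1] * dx
    return (c00 * (1 - dy) + c10 * dy) * (1 - dz) + (c01 * (1 - dy) + c11 * dy) * dz


@nb.njit(cache=True)
def _gamma_opt(
    ref_vals, ref_sp, ref_org, ev_vals, ev_sp, ev_org,
    offsets, off_r2, dta, delta_global, local_pct, use_local, cutoff, gamma_out,
):  # pragma: no cover
    nx, ny, nz = ref_vals.shape
    n_off = offsets.shape[0]
    inv_dta2 = 1.0 / (dta * dta)
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                dr = ref_vals[i, j, k]
                if np.isnan(gamma_out[i, j, k]):
                    continue  # masked out by caller
                if dr < cutoff:
                    gamma_out[i, j, k] = np.nan
                    continue
                delta = local_pct * dr if use_local else delta_global
                x = ref_org[0] + i * ref_sp[0]
                y = ref_org[1] + j * ref_sp[1]
                z = ref_org[2] + k * ref_sp[2]
                best = 1e30
                for o in range(n_off):
                    r2 = off_r2[o] * inv_dta2
                    if r2 >= best:
                        break  # offsets sorted by radius: no better point exists
                    de = _trilinear(
                        ev_vals, ev_sp, ev_org,
                        x + offsets[o, 0], y + offsets[o, 1], z + offsets[o, 2],
                    )
                    if np.isnan(de):
                        continue
                    dd = (de - dr) / delta
                    g2 = r2 + dd * dd
                    if g2 < best:
                        best = g2
                gamma_out[i, j, k] = math.sqrt(best) if best < 1e30 else np.nan


@nb.njit(cache=True)
def _gamma_brute(
    ref_vals, ref_sp, ref_org, ev_vals, ev_sp, ev_org,
    order, step, dta, delta_global, local_pct, use_local, cutoff, gamma_out,
):  # pragma: no cover
    """Exhaustive minimum over the cubic dta/10 offset lattice.

    ``order`` visits each 1D offset index by increasing magnitude
    (0, +1, -1, ...); once an axis term alone reaches the running minimum
    the remaining (larger) offsets on that axis cannot improve it, so the
    break is exact and the result equals the full lattice minimum.
    """
    nx, ny, nz = ref_vals.shape
    n_ord = order.shape[0]
    inv_dta = 1.0 / dta
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                dr = ref_vals[i, j, k]
                if np.isnan(gamma_out[i, j, k]):
                    continue
                if dr < cutoff:
                    gamma_out[i, j, k] = np.nan
                    continue
                delta = local_pct * dr if use_local else delta_global
                x = ref_org[0] + i * ref_sp[0]
                y = ref_org[1] + j * ref_sp[1]
                z = ref_org[2] + k * ref_sp[2]
                best = 1e30
                for a in range(n_ord):
                    oz = order[a]
                    rz = (oz * step * inv_dta) ** 2
                    if rz >= best:
                        break
                    for b in range(n_ord):
                        oy = order[b]
                        rzy = rz + (oy * step * inv_dta) ** 2
                        if rzy >= best:
                            break
                        for c in range(n_ord):
                            ox = order[c]
                            r2 = rzy + (ox * step * inv_dta) ** 2
                            if r2 >= best:
                                break
                            de = _trilinear(
                                ev_vals, ev_sp, ev_org,
                                x + ox * step, y + oy * step, z + oz * step,
                            )
                            if np.isnan(de):
                                continue
                            dd = (de - dr) / delta
                            g2 = r2 + dd * dd
                            if g2 < best:
                                best = g2
                gamma_out[i, j, k] = math.sqrt(best) if best < 1e30 else np.nan


def _check_overlap(reference: Grid3D, evaluated: Grid3D) -> None:
    rlo, rhi = reference.bounds()
    elo, ehi = evaluated.bounds()
    if np.any(rhi < elo) or np.any(elo > rhi) or np.any(ehi < rlo):
        raise ValueError("reference and evaluated grids do not overlap")


def _finalize(reference, gamma_vals, criteria) -> GammaResult:
    valid = np.isfinite(gamma_vals)
    n_eval = int(valid.sum())
    rate = 100.0 * float(np.mean(gamma_vals[valid] <= 1.0)) if n_eval else 0.0
    gmap = Grid3D(reference.spacing, reference.origin, np.nan_to_num(gamma_vals, nan=0.0))
    gmap.values[~valid] = np.nan  # Grid3D validates finiteness; restore NaNs after
    return GammaResult(gmap, rate, n_eval, criteria)


def _prep_gamma(reference, evaluated, criteria, mask):
    _check_overlap(reference, evaluated)
    ref_max = float(np.nanmax(reference.values if mask is None else reference.values[mask]))
    cutoff = criteria.low_dose_cutoff_pct / 100.0 * ref_max
    delta_global = criteria.dose_pct / 100.0 * ref_max
    local_pct = criteria.dose_pct / 100.0
    gamma_vals = np.zeros(reference.dims)
    if mask is not None:
        gamma_vals[~mask] = np.nan
    return cutoff, delta_global, local_pct, gamma_vals


def gamma_analysis(
    reference: DoseGrid,
    evaluated: DoseGrid,
    criteria: GammaCriteria | None = None,
    mask: np.ndarray | None = None,
) -> GammaResult:
    """3D gamma of ``evaluated`` against ``reference`` (the reference grid
    defines the evaluation lattice; grids may differ in spacing).

    The spatial search uses sub-voxel offsets of ``dta/10`` within a sphere
    of radius ``3*dta``, visited in order of increasing distance with an
    exact early-exit bound.
    """
    if criteria is None:
        criteria = GammaCriteria()
    cutoff, delta_global, local_pct, gamma_vals = _prep_gamma(
        reference, evaluated, criteria, mask
    )
    step = criteria.dta_mm / 10.0
    n = int(round(3.0 * criteria.dta_mm / step))
    grid = np.arange(-n, n + 1) * step
    ox, oy, oz = np.meshgrid(grid, grid, grid, indexing="ij")
    offs = np.column_stack([ox.ravel(), oy.ravel(), oz.ravel()])
    r2 = np.sum(offs**2, axis=1)
    keep = r2 <= (3.0 * criteria.dta_mm) ** 2 + 1e-9
    offs, r2 = offs[keep], r2[keep]
    order = np.argsort(r2, kind="stable")
    offs, r2 = np.ascontiguousarray(offs[order]), np.ascontiguousarray(r2[order])

    _gamma_opt(
        np.ascontiguousarray(reference.values), reference.spacing, reference.origin,
        np.ascontiguousarray(evaluated.values), evaluated.spacing, evaluated.origin,
        offs, r2, criteria.dta_mm, delta_global, local_pct,
        criteria.normalization == "local", cutoff, gamma_vals,
    )
    return _finalize(reference, gamma_vals, criteria)


def gamma_bruteforce(
    reference: DoseGrid,
    evaluated: DoseGrid,
    criteria: GammaCriteria | None = None,
    mask: np.ndarray | None = None,
    max_voxels: int = 64000,
) -> GammaResult:
    """Exhaustive-search gamma oracle for small grids.

    Minimizes over the full cubic lattice of offsets supersampled at
    ``dta/10`` out to ``3*dta`` per axis (plain nested loops; offsets whose
    distance term alone already exceeds the running minimum are skipped,
    which cannot change the result).  Refuses grids larger than
    ``max_voxels`` — this is a verification instrument, not the production
    path.
    """
    if criteria is None:
        criteria = GammaCriteria()
    if int(np.prod(reference.dims)) > max_voxels:
        raise ValueError("grid too large for the brute-force gamma oracle")
    cutoff, delta_global, local_pct, gamma_vals = _prep_gamma(
        reference, evaluated, criteria, mask
    )
    step = criteria.dta_mm / 10.0
    n_step = int(round(3.0 * criteria.dta_mm / step))
    order = np.zeros(2 * n_step + 1, dtype=np.int64)
    order[1::2] = np.arange(1, n_step + 1)
    order[2::2] = -np.arange(1, n_step + 1)
    _gamma_brute(
        np.ascontiguousarray(reference.values), reference.spacing, reference.origin,
        np.ascontiguousarray(evaluated.values), evaluated.spacing, evaluated.origin,
        order, step, criteria.dta_mm, delta_global, local_pct,
        criteria.normalization == "local", cutoff, gamma_vals,
    )
    return _finalize(reference, gamma_vals, criteria)


# ---------------------------------------------------------------------------
# Depth dose


@dataclass
class PDDCurve:
    depths: np.ndarray  # mm
    values: np.ndarray  # %, 100 at the normalization depth
    d_max: float  # mm
    normalization_depth: float  # mm

    def at(self, depth_mm: float) -> float:
        return float(np.interp(depth_mm, self.depths, self.values))


def extract_pdd(
    dose: DoseGrid,
    entry_mm,
    direction=(0.0, 0.0, -1.0),
    step_mm: float = 1.0,
    normalization_depth: float | None = None,
    max_depth_mm: float | None = None,
) -> PDDCurve:
    """Central-axis percentage depth dose.

    Samples trilinearly every ``step_mm`` along ``direction`` from the
    ``entry_mm`` surface point.  ``d_max`` is the depth of the (shallowest,
    on ties) maximum; the curve is normalized to 100% at
    ``normalization_depth`` — by default the first sampled depth 20 mm
    beyond ``d_max`` (i.e. within the 2-3 cm beyond-buildup band).
    """
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    entry = np.asarray(entry_mm, dtype=float)
    lo, hi = dose.bounds()
    if not dose.contains(entry + d * step_mm)[0]:
        raise ValueError("beam axis does not enter the dose grid")
    if max_depth_mm is None:
        max_depth_mm = float(np.linalg.norm(hi - lo))
    depths = np.arange(0.0, max_depth_mm + step_mm / 2, step_mm)
    pts = entry + np.outer(depths, d)
    inside = dose.contains(pts)
    depths = depths[inside]
    raw = dose.sample(pts[inside])

    i_max = int(np.argmax(raw))  # argmax returns the first (shallowest) tie
    d_max = float(depths[i_max])
    if normalization_depth is None:
        candidates = depths[depths >= d_max + 20.0]
        normalization_depth = float(candidates[0]) if len(candidates) else d_max
    norm_val = float(np.interp(normalization_depth, depths, raw))
    if norm_val <= 0:
        raise ValueError("zero dose at the normalization depth")
    return PDDCurve(depths, 100.0 * raw / norm_val, d_max, float(normalization_depth))


def roi_mean(dose: DoseGrid, center_mm, radius_mm: float) -> float:
    """Volume-weighted mean dose over a spherical ROI (partial voxels by
    3x3x3 subsampling)."""
    center = np.asarray(center_mm, dtype=float)
    lo, hi = dose.bounds()
    if np.any(center - radius_mm < lo) or np.any(center + radius_mm > hi):
        raise ValueError("ROI extends outside the dose grid")
    sp = dose.spacing
    half_diag = float(np.linalg.norm(sp)) / 2.0
    i_lo = np.floor((center - radius_mm - half_diag - dose.origin) / sp).astype(int)
    i_hi = np.ceil((center + radius_mm + half_diag - dose.origin) / sp).astype(int)
    i_lo = np.maximum(i_lo, 0)
    i_hi = np.minimum(i_hi, np.array(dose.dims) - 1)

    offs = (np.arange(3) - 1.0) / 3.0  # subvoxel offsets at +-1/3 voxel
    sub = np.stack(np.meshgrid(offs, offs, offs, indexing="ij"), -1).reshape(-1, 3) * sp

    total_w = 0.0
    total = 0.0
    for ix in range(i_lo[0], i_hi[0] + 1):
        for iy in range(i_lo[1], i_hi[1] + 1):
            for iz in range(i_lo[2], i_hi[2] + 1):
                c = dose.origin + np.array([ix, iy, iz]) * sp
                pts = c + sub
                w = np.mean(np.sum((pts - center) ** 2, axis=1) <= radius_mm**2)
                if w > 0:
                    total += w * dose.values[ix, iy, iz]
                    total_w += w
    if total_w == 0:
        raise ValueError("empty ROI")
    return total / total_w


def surface_exclusion(
    body_mask: np.ndarray, spacing, margin_mm: float = 7.0
) -> np.ndarray:
    """Erode the body mask by a ball of ``margin_mm`` (grid-metric), i.e.
    exclude the outermost surface layer from analysis."""
    from scipy.ndimage import distance_transform_edt

    if margin_mm < 0:
        raise ValueError("margin must be >= 0")
    if margin_mm == 0:
        return body_mask.copy()
    dist = distance_transform_edt(body_mask, sampling=np.asarray(spacing, dtype=float))
    return dist > margin_mm


def report(comparisons: list[dict]) -> pd.DataFrame:
    """Pass-rate table shaped like the validation summaries.

    Each comparison dict needs ``plan`` and ``mode`` keys plus one key per
    criteria label (e.g. ``"3%G/2 mm"``) holding a passing rate in percent.
    Rates keep full precision in the frame (round only for text output).
    """
    if not comparisons:
        raise ValueError("no comparisons to report")
    df = pd.DataFrame(comparisons)
    lead = [c for c in ("plan", "mode") if c in df.columns]
    return df[lead + [c for c in df.columns if c not in lead]]


def report_text(df: pd.DataFrame) -> str:
    """Fixed-precision text rendering of a report (rates to 0.1%)."""
    shown = df.copy()
    for c in shown.columns:
        if shown[c].dtype.kind == "f":
            shown[c] = shown[c].map(lambda v: f"{v:.1f}")
    return shown.to_string(index=False)
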