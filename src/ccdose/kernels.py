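"""Energy-deposition kernels, collapsed cones, and cumulative-cumulative tables.

The water point kernel h(theta, r) — the fraction of released energy
deposited per (zenith angle, radius) bin around a primary interaction —
is tabulated at high resolution (1 mm, 1 degree) from an analytic
poly-exponential surrogate fitted to the qualitative shape of published
Monte Carlo water point kernels: a forward-peaked angular distribution and,
per angle, a short "primary electron" exponential whose range grows with
photon energy plus a longer photon-scatter tail.  Vendor Monte Carlo
kernels are proprietary; these surrogates carry no fidelity claim beyond
their documented structure.

The angular dependence is discretized with a collapsed-cone approximation;
radial deposition uses the cumulative-cumulative kernel (CCK) so that
voxel-sized radial intervals receive exact bin-averaged energy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "KernelTable",
    "CCKTable",
    "CCKStack",
    "ConeSet",
    "analytic_point_kernel",
    "build_cck",
    "build_cck_stack",
    "make_cone_set",
]


@dataclass
class KernelTable:
    """Point kernel: fraction of released energy per (zenith, radius) bin in water."""

    zenith_edges_deg: np.ndarray  # (n_theta + 1,)
    radius_edges_mm: np.ndarray  # (n_r + 1,)
    k: np.ndarray  # (n_theta, n_r), sums to 1

    def __post_init__(self) -> None:
        self.zenith_edges_deg = np.asarray(self.zenith_edges_deg, dtype=float)
        self.radius_edges_mm = np.asarray(self.radius_edges_mm, dtype=float)
        self.k = np.asarray(self.k, dtype=float)
        if np.any(self.k < 0):
            raise ValueError("kernel fractions must be >= 0")


def analytic_point_kernel(
    energy_mev: float,
    radius_max_mm: float = 60.0,
    dr_mm: float = 1.0,
    dtheta_deg: float = 1.0,
) -> KernelTable:
    """Analytic surrogate water point kernel for a given photon energy.

    Angular density ~ sin(theta) * exp(-theta / theta0(E)) with theta0
    shrinking as energy grows (more forward-peaked); radial density per
    angle mixes a primary-electron exponential of range ~5E mm scaled by
    direction (longer forward) with a 18 mm scatter tail.  The table is
    renormalized to unity within the tabulated reach.
    """
    th_edges = np.arange(0.0, 180.0 + dtheta_deg / 2, dtheta_deg)
    r_edges = np.arange(0.0, radius_max_mm + dr_mm / 2, dr_mm)
    th_c = np.radians((th_edges[:-1] + th_edges[1:]) / 2.0)

    theta0 = np.radians(30.0 / (0.5 + 0.7 * np.sqrt(energy_mev)))
    ang = np.sin(th_c) * np.exp(-th_c / theta0)
    ang = ang / ang.sum()

    # direction-dependent primary range: full ahead, short behind
    r_primary = np.maximum(1.0, 5.0 * energy_mev * (0.15 + 0.85 * (1 + np.cos(th_c)) / 2.0))
    r_scatter = 18.0
    frac_scatter = 0.3

    e1 = np.exp(-r_edges[None, :] / r_primary[:, None])  # (n_theta, n_r+1)
    e2 = np.exp(-r_edges[None, :] / r_scatter)
    radial = (1 - frac_scatter) * (e1[:, :-1] - e1[:, 1:]) + frac_scatter * (
        e2[None, :, :-1] - e2[None, :, 1:]
    )[0]
    k = ang[:, None] * radial
    k = k / k.sum()
    return KernelTable(th_edges, r_edges, k)


# ---------------------------------------------------------------------------
# Collapsed cones

#: Default zenith bin edges (degrees): fine forward, coarse backward, since
#: the kernel is strongly forward-peaked at therapy energies.
DEFAULT_ZENITH_EDGES = np.array([0.0, 6.0, 12.0, 20.0, 30.0, 45.0, 70.0, 110.0, 180.0])


@dataclass
class ConeSet:
    """Collapsed-cone axis directions (kernel frame: +z is forward).

    ``directions`` has one unit vector per (zenith bin, azimuth); solid-angle
    ``weights`` sum to 1 over the sphere.
    """

    zenith_edges_deg: np.ndarray
    n_azimuth: int
    directions: np.ndarray  # (n_cones, 3)
    zenith_bin: np.ndarray  # (n_cones,) int
    weights: np.ndarray  # (n_cones,) solid-angle fractions

    @property
    def n_zenith(self) -> int:
        return len(self.zenith_edges_deg) - 1


def make_cone_set(
    zenith_edges_deg: np.ndarray | None = None, n_azimuth: int = 6
) -> ConeSet:
    if zenith_edges_deg is None:
        zenith_edges_deg = DEFAULT_ZENITH_EDGES
    edges = np.asarray(zenith_edges_deg, dtype=float)
    n_z = len(edges) - 1
    dirs = []
    zbin = []
    weights = []
    for zi in range(n_z):
        lo, hi = np.radians(edges[zi]), np.radians(edges[zi + 1])
        # solid-angle centroid zenith of the bin
        theta = np.arccos(np.clip((np.cos(lo) + np.cos(hi)) / 2.0, -1.0, 1.0))
        omega = (np.cos(lo) - np.cos(hi)) / 2.0  # fraction of 4pi
        for ai in range(n_azimuth):
            phi = 2 * np.pi * (ai + 0.5) / n_azimuth
            dirs.append(
                [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)]
            )
            zbin.append(zi)
            weights.append(omega / n_azimuth)
    return ConeSet(edges, n_azimuth, np.array(dirs), np.array(zbin, dtype=np.int64), np.array(weights))


# ---------------------------------------------------------------------------
# Cumulative-cumulative kernel


@dataclass
class CCKTable:
    """Per-cone doubly cumulative deposition vs radiological radius.

    ``ck[z, j]`` is the cumulative energy fraction of zenith bin ``z``
    within radius ``r_edges[j]``; ``cck`` is its radius integral (exact,
    treating the tabulated kernel as piecewise-constant radial density).
    Both are nondecreasing; ``ck[z, -1]`` is the bin's total energy
    fraction and all bins together sum to 1.
    """

    zenith_edges_deg: np.ndarray
    r_edges: np.ndarray  # (n_r + 1,)
    ck: np.ndarray  # (n_z, n_r + 1)
    cck: np.ndarray  # (n_z, n_r + 1)
    energy_mev: float | None = None

    @property
    def reach(self) -> float:
        return float(self.r_edges[-1])

    def interval_mass(self, zenith_bin: int, a: float, b: float) -> float:
        """Energy fraction deposited in radiological interval [a, b] of one
        cone bin, from CCK differences (exact bin-averaged deposition)."""
        return self.ck_at(zenith_bin, b) - self.ck_at(zenith_bin, a)

    def ck_at(self, zenith_bin: int, r: float) -> float:
        r_e = self.r_edges
        if r <= 0:
            return 0.0
        if r >= r_e[-1]:
            return float(self.ck[zenith_bin, -1])
        j = int(np.searchsorted(r_e, r, side="right") - 1)
        dens = (self.ck[zenith_bin, j + 1] - self.ck[zenith_bin, j]) / (r_e[j + 1] - r_e[j])
        return float(self.ck[zenith_bin, j] + dens * (r - r_e[j]))

    def cck_at(self, zenith_bin: int, r: float) -> float:
        r_e = self.r_edges
        if r <= 0:
            return 0.0
        if r >= r_e[-1]:
            return float(self.cck[zenith_bin, -1] + self.ck[zenith_bin, -1] * (r - r_e[-1]))
        j = int(np.searchsorted(r_e, r, side="right") - 1)
        h = r - r_e[j]
        dens = (self.ck[zenith_bin, j + 1] - self.ck[zenith_bin, j]) / (r_e[j + 1] - r_e[j])
        return float(self.cck[zenith_bin, j] + self.ck[zenith_bin, j] * h + 0.5 * dens * h * h)

    def fine_tables(self, df: float = 0.25) -> tuple[np.ndarray, np.ndarray, float]:
        """(cck_fine (n_z, n_fine), end slopes (n_z,), df) for the numba loop."""
        n_fine = int(np.floor(self.reach / df)) + 1
        r = np.arange(n_fine) * df
        out = np.empty((self.ck.shape[0], n_fine))
        for z in range(self.ck.shape[0]):
            out[z] = [self.cck_at(z, rv) for rv in r]
        return out, self.ck[:, -1].copy(), df


def build_cck(
    kernel: KernelTable,
    zenith_edges_deg: np.ndarray | None = None,
    renormalize: bool = True,
) -> CCKTable:
    """Collapse a fine kernel into zenith bins and doubly cumulate over radius.

    Per collapsed cone bin the radial fractions are first cumulated (CK)
    and the CK is then integrated again (CCK); because the tabulated kernel
    is a piecewise-constant radial density, both integrals are exact
    (piecewise linear / piecewise quadratic).  Kernels whose total differs
    from 1 are renormalized with a warning.
    """
    import warnings

    if zenith_edges_deg is None:
        zenith_edges_deg = DEFAULT_ZENITH_EDGES
    edges = np.asarray(zenith_edges_deg, dtype=float)

    k = kernel.k
    total = k.sum()
    if not np.isclose(total, 1.0, atol=1e-6):
        warnings.warn(f"kernel total {total:.6f} != 1; renormalizing", stacklevel=2)
        if renormalize and total > 0:
            k = k / total

    th_centers = (kernel.zenith_edges_deg[:-1] + kernel.zenith_edges_deg[1:]) / 2.0
    n_z = len(edges) - 1
    row_bin = np.clip(np.searchsorted(edges, th_centers, side="right") - 1, 0, n_z - 1)
    collapsed = np.zeros((n_z, k.shape[1]))
    for row, b in enumerate(row_bin):
        collapsed[b] += k[row]

    r_e = kernel.radius_edges_mm
    dr = np.diff(r_e)
    ck = np.zeros((n_z, len(r_e)))
    ck[:, 1:] = np.cumsum(collapsed, axis=1)
    cck = np.zeros_like(ck)
    # integral of a piecewise-linear CK: trapezoid is exact
    cck[:, 1:] = np.cumsum((ck[:, :-1] + ck[:, 1:]) / 2.0 * dr, axis=1)
    return CCKTable(edges, r_e, ck, cck)


@dataclass
class CCKStack:
    """Energy-indexed CCK tables for hardening-aware superposition.

    ``kernel_index(mean_energy)`` picks the nearest tabulated kernel for a
    voxel's recorded mean interacting-photon energy.
    """

    energies: np.ndarray
    tables: list[CCKTable]

    def kernel_index(self, mean_energy: np.ndarray) -> np.ndarray:
        me = np.asarray(mean_energy, dtype=float)
        return np.argmin(np.abs(me[..., None] - self.energies), axis=-1).astype(np.int8)

    def fine_tables(self, df: float = 0.25):
        fines = []
        ends = []
        for t in self.tables:
            f, e, _ = t.fine_tables(df)
            fines.append(f)
            ends.append(e)
        return np.stack(fines), np.stack(ends), df

    @property
    def reach(self) -> float:
        return self.tables[0].reach


#: Tabulated kernel energies (MeV) spanning the surrogate spectra's
#: release-weighted mean energies.
DEFAULT_KERNEL_ENERGIES = np.array([0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 4.0, 6.0, 8.0, 12.0])

_STACK_CACHE: dict[tuple, CCKStack] = {}


def build_cck_stack(
    energies: np.ndarray | None = None,
    zenith_edges_deg: np.ndarray | None = None,
    radius_max_mm: float = 60.0,
) -> CCKStack:
    if energies is None:
        energies = DEFAULT_KERNEL_ENERGIES
    if zenith_edges_deg is None:
        zenith_edges_deg = DEFAULT_ZENITH_EDGES
    key = (tuple(np.round(energies, 6)), tuple(np.round(zenith_edges_deg, 6)), radius_max_mm)
    if key not in _STACK_CACHE:
        tables = []
        for e in energies:
            t = build_cck(analytic_point_kernel(e, radius_max_mm), zenith_edges_deg)
            t.energy_mev = float(e)
            tables.append(t)
        _STACK_CACHE[key] = CCKStack(np.asarray(energies, dtype=float), tables)
    return _STACK_CACHE[key]
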