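"""Numba inner loops: Siddon-style ray traversal and collapsed-cone collection.

These are implementation details; the public surfaces live in
:mod:`ccdose.terma` and :mod:`ccdose.superposition`.
"""

from __future__ import annotations

import math

import numba as nb
import numpy as np


@nb.njit(cache=True)
def ray_path_ed(ed, sp, org, p0, p1):  # pragma: no cover - exercised via wrappers
    """Line integral of ED from p0 to p1 (mm water-equivalent).

    Exact voxel traversal: the segment is clipped to the grid bounding box
    and walked boundary-to-boundary, accumulating ED * segment length.
    Segments outside the grid contribute zero.
    """
    dx = p1[0] - p0[0]
    dy = p1[1] - p0[1]
    dz = p1[2] - p0[2]
    length = math.sqrt(dx * dx + dy * dy + dz * dz)
    if length == 0.0:
        return 0.0

    nx, ny, nz = ed.shape
    # clip to bounding box (voxel outer faces), slab method in parameter t
    t0 = 0.0
    t1 = 1.0
    for ax in range(3):
        if ax == 0:
            d, p, n = dx, p0[0], nx
        elif ax == 1:
            d, p, n = dy, p0[1], ny
        else:
            d, p, n = dz, p0[2], nz
        lo = org[ax] - 0.5 * sp[ax]
        hi = org[ax] + (n - 0.5) * sp[ax]
        if d == 0.0:
            if p < lo or p > hi:
                return 0.0
        else:
            ta = (lo - p) / d
            tb = (hi - p) / d
            if ta > tb:
                ta, tb = tb, ta
            if ta > t0:
                t0 = ta
            if tb < t1:
                t1 = tb
    if t0 >= t1:
        return 0.0

    eps = 1e-9
    # entry voxel (nudge inside)
    tm = t0 + eps
    ix = int(math.floor((p0[0] + tm * dx - (org[0] - 0.5 * sp[0])) / sp[0]))
    iy = int(math.floor((p0[1] + tm * dy - (org[1] - 0.5 * sp[1])) / sp[1]))
    iz = int(math.floor((p0[2] + tm * dz - (org[2] - 0.5 * sp[2])) / sp[2]))
    if ix < 0:
        ix = 0
    if iy < 0:
        iy = 0
    if iz < 0:
        iz = 0
    if ix > nx - 1:
        ix = nx - 1
    if iy > ny - 1:
        iy = ny - 1
    if iz > nz - 1:
        iz = nz - 1

    big = 1e30
    # parametric distance to the next boundary crossing per axis
    if dx > 0:
        t_next_x = ((org[0] + (ix + 0.5) * sp[0]) - p0[0]) / dx
        t_step_x = sp[0] / dx
        step_x = 1
    elif dx < 0:
        t_next_x = ((org[0] + (ix - 0.5) * sp[0]) - p0[0]) / dx
        t_step_x = -sp[0] / dx
        step_x = -1
    else:
        t_next_x = big
        t_step_x = big
        step_x = 0
    if dy > 0:
        t_next_y = ((org[1] + (iy + 0.5) * sp[1]) - p0[1]) / dy
        t_step_y = sp[1] / dy
        step_y = 1
    elif dy < 0:
        t_next_y = ((org[1] + (iy - 0.5) * sp[1]) - p0[1]) / dy
        t_step_y = -sp[1] / dy
        step_y = -1
    else:
        t_next_y = big
        t_step_y = big
        step_y = 0
    if dz > 0:
        t_next_z = ((org[2] + (iz + 0.5) * sp[2]) - p0[2]) / dz
        t_step_z = sp[2] / dz
        step_z = 1
    elif dz < 0:
        t_next_z = ((org[2] + (iz - 0.5) * sp[2]) - p0[2]) / dz
        t_step_z = -sp[2] / dz
        step_z = -1
    else:
        t_next_z = big
        t_step_z = big
        step_z = 0

    total = 0.0
    t = t0
    while t < t1 - eps:
        tn = t_next_x
        axis = 0
        if t_next_y < tn:
            tn = t_next_y
            axis = 1
        if t_next_z < tn:
            tn = t_next_z
            axis = 2
        if tn > t1:
            tn = t1
            axis = -1
        total += ed[ix, iy, iz] * (tn - t) * length
        t = tn
        if axis == 0:
            ix += step_x
            t_next_x += t_step_x
            if ix < 0 or ix >= nx:
                break
        elif axis == 1:
            iy += step_y
            t_next_y += t_step_y
            if iy < 0 or iy >= ny:
                break
        elif axis == 2:
            iz += step_z
            t_next_z += t_step_z
            if iz < 0 or iz >= nz:
                break
        else:
            break
    return total


@nb.njit(cache=True)
def ray_paths_ed(ed, sp, org, p0s, p1s):  # pragma: no cover
    n = p0s.shape[0]
    out = np.empty(n)
    for i in range(n):
        out[i] = ray_path_ed(ed, sp, org, p0s[i], p1s[i])
    return out


@nb.njit(cache=True, inline="always")
def _cck_interp(row, n_fine, df, end_slope, t):  # pragma: no cover
    """Doubly cumulative kernel value at radiological radius t (linear
    extrapolation with the terminal cumulative slope beyond the reach)."""
    if t <= 0.0:
        return 0.0
    j = t / df
    ij = int(j)
    if ij >= n_fine - 1:
        return row[n_fine - 1] + end_slope * (t - (n_fine - 1) * df)
    w = j - ij
    return row[ij] * (1.0 - w) + row[ij + 1] * w


@nb.njit(cache=True)
def collect_dose(
    ed,
    terma,
    kidx,
    mask_idx,
    sp,
    org,
    cck_fine,
    ck_end,
    df,
    rmax,
    cone_local,
    cone_zbin,
    inv_naz,
    tilt,
    src,
    beam_dir,
    step,
    max_geom,
    dose,
):  # pragma: no cover - exercised via superpose
    """Voxel-centric collapsed-cone collection.

    For every dose voxel and cone direction, march upstream in geometric
    steps, accumulate radiological distance, and collect TERMA weighted by
    increments of the voxel-averaged cumulative kernel (CCK differences).
    ``cck_fine``: (n_kernels, n_zenith, n_fine) doubly cumulative kernel on
    a uniform fine radius grid; ``ck_end``: terminal cumulative slope.
    """
    n_fine = cck_fine.shape[2]
    n_cones = cone_local.shape[0]
    nvox = mask_idx.shape[0]
    nx, ny, nz = ed.shape

    for n in range(nvox):
        ix = mask_idx[n, 0]
        iy = mask_idx[n, 1]
        iz = mask_idx[n, 2]
        px = org[0] + ix * sp[0]
        py = org[1] + iy * sp[1]
        pz = org[2] + iz * sp[2]
        rho_i = ed[ix, iy, iz]
        delta = 0.5 * step * max(rho_i, 0.05)
        ki = kidx[ix, iy, iz]

        # kernel forward axis: central beam direction, or tilted along the
        # local source->voxel ray
        if tilt:
            ax0 = px - src[0]
            ax1 = py - src[1]
            ax2 = pz - src[2]
            norm = math.sqrt(ax0 * ax0 + ax1 * ax1 + ax2 * ax2)
            if norm > 0:
                ax0 /= norm
                ax1 /= norm
                ax2 /= norm
            else:
                ax0, ax1, ax2 = beam_dir[0], beam_dir[1], beam_dir[2]
        else:
            ax0, ax1, ax2 = beam_dir[0], beam_dir[1], beam_dir[2]

        # orthonormal basis (e1, e2, axis)
        if abs(ax2) < 0.9:
            h0, h1, h2 = 0.0, 0.0, 1.0
        else:
            h0, h1, h2 = 1.0, 0.0, 0.0
        e10 = ax1 * h2 - ax2 * h1
        e11 = ax2 * h0 - ax0 * h2
        e12 = ax0 * h1 - ax1 * h0
        nrm = math.sqrt(e10 * e10 + e11 * e11 + e12 * e12)
        e10 /= nrm
        e11 /= nrm
        e12 /= nrm
        e20 = ax1 * e12 - ax2 * e11
        e21 = ax2 * e10 - ax0 * e12
        e22 = ax0 * e11 - ax1 * e10

        acc = 0.0
        for c in range(n_cones):
            lx = cone_local[c, 0]
            ly = cone_local[c, 1]
            lz = cone_local[c, 2]
            dx = e10 * lx + e20 * ly + ax0 * lz
            dy = e11 * lx + e21 * ly + ax1 * lz
            dz = e12 * lx + e22 * ly + ax2 * lz
            zb = cone_zbin[c]
            row = cck_fine[ki, zb]
            slope = ck_end[ki, zb]

            t = 0.0
            s = 0.0
            ckbar_prev = _cck_interp(row, n_fine, df, slope, delta) / (2.0 * delta)
            # self-deposition of the collector's own released energy
            acc += terma[ix, iy, iz] * ckbar_prev * inv_naz
            while t < rmax and s < max_geom:
                xm = px - (s + 0.5 * step) * dx
                ym = py - (s + 0.5 * step) * dy
                zm = pz - (s + 0.5 * step) * dz
                jx = int(round((xm - org[0]) / sp[0]))
                jy = int(round((ym - org[1]) / sp[1]))
                jz = int(round((zm - org[2]) / sp[2]))
                if jx < 0 or jx >= nx or jy < 0 or jy >= ny or jz < 0 or jz >= nz:
                    break
                rho = ed[jx, jy, jz]
                dt = rho * step
                if dt > 1e-12:
                    tn = t + dt
                    up = _cck_interp(row, n_fine, df, slope, tn + delta)
                    dn = _cck_interp(row, n_fine, df, slope, tn - delta)
                    ckbar_new = (up - dn) / (2.0 * delta)
                    w = ckbar_new - ckbar_prev
                    if w > 0.0:
                        acc += terma[jx, jy, jz] * w * inv_naz
                    ckbar_prev = ckbar_new
                    t = tn
                s += step
        dose[ix, iy, iz] += acc
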