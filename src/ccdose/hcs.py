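"""Heterogeneity-Compensated Superposition (HCS) density pre-filter.

HCS is an optional, deliberately *nonphysical* correction: before the
superposition step (and only there — TERMA always sees the raw density),
the density volume is filtered near material interfaces in a position- and
direction-sensitive way, which changes how far the kernel spreads around
interfaces and thereby the dose in and near low-density regions.

The published description gives no filter formula, so the filter here is an
original parameterized stand-in with the stated character: along lines
parallel to the beam direction, every ED step of at least
``interface_threshold`` marks an interface, and voxels within ``window_mm``
of it are blended one-sidedly toward the density flanking the *other* side
with weight ``0.5 * strength * exp(-d / (window/3))``.  Strength 0 is the
identity; voxels farther than the window from every interface are unchanged
bit-exactly; blended values always stay between the two flanking densities.

Default OFF in the engine: the correction is known to help in slab-like
geometries but not universally, so routine use is not recommended.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_model import DensityVolume

__all__ = ["HCSParams", "apply_hcs"]


@dataclass
class HCSParams:
    window_mm: float = 10.0
    strength: float = 0.5
    interface_threshold: float = 0.2  # ED step that triggers filtering

    def __post_init__(self) -> None:
        if self.window_mm < 0:
            raise ValueError("window_mm must be >= 0")
        if not 0.0 <= self.strength <= 1.0:
            raise ValueError("strength must lie in [0, 1]")


def apply_hcs(
    density: DensityVolume, beam_direction: np.ndarray, params: HCSParams
) -> DensityVolume:
    """Filtered copy of the density for use by superposition only.

    Filtering runs along grid columns of the axis closest to
    ``beam_direction`` (exact for axis-aligned beams; oblique directions
    snap to the dominant axis).
    """
    g = density.grid
    ed = g.values.copy()
    if params.strength == 0.0 or params.window_mm == 0.0:
        return DensityVolume(g.copy(values=ed), density.body_mask.copy())

    direction = np.asarray(beam_direction, dtype=float)
    axis = int(np.argmax(np.abs(direction)))
    sp = float(g.spacing[axis])

    # work with the filtered axis last
    work = np.moveaxis(ed, axis, -1)
    n = work.shape[-1]
    n_win = int(np.floor(params.window_mm / sp + 0.5))
    lam = params.window_mm / 3.0

    steps = np.abs(np.diff(work, axis=-1))
    for k in np.flatnonzero(np.any(steps >= params.interface_threshold, axis=tuple(range(work.ndim - 1)))):
        cols = steps[..., k] >= params.interface_threshold  # interface between k, k+1
        if not np.any(cols):
            continue
        near_lo = work[..., k][cols]  # flank on the low-index side
        near_hi = work[..., k + 1][cols]
        for off in range(n_win):
            d = (off + 0.5) * sp
            if d > params.window_mm:
                break
            w = 0.5 * params.strength * np.exp(-d / lam)
            j_lo = k - off
            if j_lo >= 0:
                vals = work[..., j_lo][cols]
                work[..., j_lo][cols] = (1.0 - w) * vals + w * near_hi
            j_hi = k + 1 + off
            if j_hi < n:
                vals = work[..., j_hi][cols]
                work[..., j_hi][cols] = (1.0 - w) * vals + w * near_lo
    out = np.moveaxis(work, -1, axis)
    return DensityVolume(g.copy(values=out), density.body_mask.copy())
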