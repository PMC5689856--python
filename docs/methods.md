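# Methods

`ccdose` implements a CPU superposition/convolution (S/C) photon dose
engine of the kind used for independent verification of IMRT/VMAT plans,
together with the comparison instruments needed to validate it.  This note
records the model, its assumptions, the numerical choices, and what the
synthetic test conditions do and do not demonstrate.

## Coordinate and unit conventions

Right-handed frame, millimetres, isocenter at the origin.  Grids store
voxel-center values; `origin` is the center of voxel (0, 0, 0); indices are
0-based.  For gantry angle 0 the source is at (0, 0, +SAD) and the beam
travels along −z; the gantry rotates about +y (patient superior–inferior).
Relative electron density (ED, water = 1) is the engine's density variable;
it attenuates the primary fluence and also stands in for relative mass
density wherever a mass weighting is needed (the distinction is below the
fidelity level of the surrogate beam data).

## The dose calculation chain

The calculation has the classic three steps.

**1. Fluence.**  A two-photon-source head model plus an electron
contamination channel:

- *Primary*: point source with a 16-bin spectrum and a sampled radial
  intensity profile (flat for the flattened 6/15 MV surrogates, falling for
  the 10 MV FFF surrogate).  Per fluence pixel (1 mm at isocenter by
  default): `mu x profile(r) x transmission(u, v)` per spectrum bin.
- *Collimation*: jaws transmit `jaw_transmission` (0.002) outside the
  opening.  MLC leaves transmit `exp(-mu_leaf * thickness)`; the rounded
  leaf end contributes the vertical chord through a cylinder of the
  configured leaf-end radius (80 mm) capped at the leaf height (70 mm), so
  transmission falls monotonically from 1 at the nominal tip to the
  leaf-body value ~8 mm behind it.  A tongue-and-groove strip (1 mm) along
  each leaf-side boundary takes the more-blocking of the two adjacent rows'
  transmissions — conservative, and sufficient to reproduce
  tongue-and-groove underdose between complementary segments.
- *Extrafocal (head scatter)*: a Gaussian plane source below the focal
  spot, realized as the in-aperture primary convolved with the projected
  source Gaussian and scaled by `extrafocal_fraction` (0.05).  It spills
  beyond the geometric edge and is partially obscured by small apertures,
  which is what drives output-factor falloff for small MLC fields.
- *Electron contamination*: a broadly blurred copy of the aperture carried
  as a separate channel; it deposits as a surface term
  `amplitude x exp(-depth_we / depth_constant)` (amplitude 0.04, constant
  15 mm) scaled to the open-field released-energy level.  The functional
  form is a package choice; only the source's existence, not its shape, is
  dictated by the head-model structure.

**2. TERMA.**  For every voxel and bin:

    T += Psi_b(u, v) * (mu/rho)_mat(ED),b * E_b * exp(-(mu/rho)_w,b * d_we) * (SAD/r)^2

with `d_we` the exact Siddon-style voxel-traversal line integral of ED from
the source, evaluated per voxel center (one trace per voxel).  Transport
uses *water* mass attenuation with the ED-weighted path (effective
pathlength); the local release factor uses the coefficients of the material
blended at the voxel's ED from the nine-material table.  Bin-wise
attenuation of the 16-bin spectrum *is* the beam-hardening mechanism; the
release-weighted mean photon energy is recorded per voxel and the spectrum
mean rises with depth as the soft bins burn off.

**3. Superposition.**  The water point kernel h(θ, r) — fraction of
released energy deposited per (zenith, radius) bin — is tabulated at
1 mm / 1° from an analytic poly-exponential surrogate (see below),
collapsed into zenith cones (default 8 zenith bins, finer forward, times
6 azimuths = 48 cones), cumulated twice over radius (CK, then CCK).  Dose
is collected voxel-centrically: for each dose voxel and cone the engine
marches upstream in steps of the voxel size, accumulates *radiological*
distance, and collects TERMA weighted by increments of the voxel-averaged
cumulative kernel `CKbar(t) = (CCK(t+δ) - CCK(t-δ)) / 2δ` with δ half the
collector's radiological step — the cumulative-cumulative construction
that suppresses voxelization error, including the collector's own
self-deposition at t = 0.  Per-cone telescoping of the CK increments makes
energy bookkeeping exact in uniform media and within 1% for contained
kernels generally.  With tilting on (default for divergent beams), the
cone axes are rotated per voxel so the kernel's forward axis follows the
local source→voxel ray.  Hardening-aware kernel choice: each voxel uses
the tabulated kernel nearest its recorded mean interacting-photon energy
(stack at 0.5–12 MeV).

**Plans and arcs.**  Static plans run fluence→TERMA→superposition per
segment and sum (dose is exactly linear in MU).  Arcs accumulate TERMA
every 2° of gantry (sector MU interpolated from the control-point
cumulative MU; aperture of the nearest control point) and superpose the
accumulated TERMA every 5° — TERMA is far cheaper than superposition, so
the split buys arc speed at negligible cost.  A full 360° arc therefore
performs 180 TERMA and 72 superposition evaluations.

**Calibration.**  `calibrate_output` runs the engine once at reference
conditions (10 × 10 cm² open field, water cube with its surface at the
reference SSD, reference point at isocenter depth 100 mm) and stores the
scalar that maps engine units to the configured Gy/MU.  Because the same
engine recomputes the reference dose, the closure is exact up to floating
point; recalibration is idempotent.

## Surrogate data

Vendor beam data (spectra, profiles, MC kernels, the nine-material table)
are proprietary, so the package ships self-authored surrogates, each
labeled as such:

- *Spectra*: 16 bins at 0.25–15 MeV with `E^p exp(-E/T)` shapes truncated
  at the nominal energy, giving release-weighted mean energies of ≈1.9,
  2.7 and 4.9 MeV for 6 MV, 10 MV FFF and 15 MV.  These produce realistic
  d_max (≈18 / 23 / 29 mm) and PDD(10 cm) ordering without claiming
  machine fidelity.
- *Materials*: nine entries (air … metal surrogate) with water anchored to
  standard published photon cross-section values and the others scaled by
  smooth energy-dependent factors; blending is linear in ED between
  neighbors, clamped outside the table, exact at each node.
- *Kernels*: angular density `sin θ · exp(-θ/θ0(E))` with θ0 shrinking as
  energy grows; radial density per angle mixes a primary-electron
  exponential of range ≈5·E mm (shortened backward) with an 18 mm scatter
  tail; renormalized within the 60 mm tabulated reach.  The shapes are
  qualitative matches to published water point kernels — claims about them
  in the test suite are engine-internal properties (normalization,
  conservation, scaling), never fidelity claims.

## HCS density filter

The heterogeneity-compensated superposition mode filters the density seen
*only* by superposition (TERMA always uses raw density).  Along grid
columns of the axis nearest the beam direction, any ED step ≥ the
interface threshold (0.2) marks an interface; voxels within the window
(10 mm) are blended toward the flanking density of the opposite side with
weight `0.5 · strength · exp(-d / (window/3))`.  Strength 0 is the
identity, voxels beyond the window are bit-exact unchanged, and blended
values stay between the two flanking densities.  The published correction
this emulates is unpublished in detail; this filter is an original
parameterized stand-in with the same stated character (position- and
direction-sensitive, superposition-only).  It raises the
laterally-disequilibrated in-lung dose of a small high-energy field toward
the equilibrium level while leaving the homogeneous entrance region
essentially unchanged.  It is off by default: such corrections are known
not to improve accuracy universally.

## Comparison instruments

- *Gamma*: reference-lattice evaluation, trilinear interpolation of the
  evaluated grid, sub-voxel search at dta/10 steps within a 3·dta radius.
  The production path visits sphere offsets sorted by distance with an
  exact early-exit bound; the brute-force oracle exhaustively minimizes
  over the full cubic lattice (with exact bound pruning that cannot change
  the minimum) and refuses large grids.  The low-dose cutoff applies to
  the reference grid; global normalization uses the reference maximum
  (within the mask when one is supplied).
- *PDD*: trilinear axis sampling at 1 mm; d_max ties resolve to the
  shallowest depth; normalization defaults to the first sampled depth
  20 mm beyond d_max (the 2–3 cm beyond-build-up band).
- *ROI mean*: volume-weighted voxel mean with partial voxels by 3³
  subsampling.
- *Surface exclusion*: Euclidean distance transform of the body mask with
  grid-metric sampling; keep distance > margin (default 7 mm).
- *Report*: pandas table of passing rates per plan/mode/criteria; full
  precision in the frame, 0.1% rounding only in text rendering.

## Numerical choices and degenerate inputs

- Collection march step = min grid spacing; geometric march capped at 3×
  the kernel reach (in very low density the radiological reach is then
  truncated; the residual tail mass is negligible at lung densities over
  slab-like extents).  Voxels outside the grid terminate the march
  (phantoms are convex).
- Cone set: 8 zenith bins with edges {0, 6, 12, 20, 30, 45, 70, 110,
  180}° × 6 azimuths.  Doubling to 16 × 12 changes the water PDD beyond
  build-up by < 0.2%, so the default is converged at the 1% level.
- Fluence plane spacing 1 mm at isocenter (resolves leaf ends); dose grid
  2.5 mm isotropic by convention, though every routine accepts arbitrary
  anisotropic spacings and the test suite mostly runs at 5 mm laterally
  for speed.
- CT→ED conversion: piecewise linear with end clamping; zero-length rays,
  empty plans (zero grid + warning), zero-area apertures (transmission-only
  fluence) and flat PDD peaks (shallowest depth) are all defined rather
  than errors.
- DICOM RT Dose support is deliberately narrow: single-frame-of-reference
  GRID doses with uniform GridFrameOffsetVector; anything else is a format
  error naming the offending tag.  The internal `.ccd` format (JSON header
  + little-endian float32, x-fastest) round-trips metadata exactly and
  values to float32 precision.

## Problem sizes

The shipped tests and the acceptance script run the engine at 5 mm lateral
/ 2.5 mm depth resolution on 10–25 cm phantoms with 48 cones — small
enough to run in minutes on one CPU, large enough that every property
checked (calibration closure, attenuation/inverse-square limits, energy
conservation, O'Connor density scaling, interface behavior, arc
bookkeeping) is resolution-converged at the stated tolerances.

## What the synthetic conditions do not show

The phantoms are noise-free, convex, and axis-aligned; the beam data are
surrogates; there is no couch, collimator rotation, or non-coplanar
geometry; MLC modeling omits interleaf leakage beyond the single
tongue-and-groove strip.  Passing tests therefore demonstrate the
*internal correctness* of the S/C machinery (its limits, invariances and
bookkeeping), not agreement with any specific linac, treatment planning
system, or measurement campaign — reproducing clinical validation numbers
would require the vendor beam model, physical measurements, and
machine-specific Monte Carlo, all outside this package's scope.

## Known limitations

- HCS along oblique beams snaps to the dominant grid axis.
- Arc apertures are taken from the nearest control point rather than
  interpolating leaf positions across the sector.
- The kernel stack shares one tabulated reach (60 mm); large-cavity or
  very-low-density geometries would need a longer table.
- Collection-mode tilting orients the kernel by the collector's ray, the
  standard reciprocity approximation.
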