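# ccdose

A CPU collapsed-cone superposition/convolution photon dose engine with the
verification toolkit used for independent checking of IMRT/VMAT plans.

## Who this is for

Medical-physics software people who need a transparent, testable
superposition/convolution (S/C) dose engine: for studying algorithm
behavior (heterogeneity handling, kernel discretization, arc
discretization), for building patient-specific QA tooling (gamma analysis,
depth-dose and point-dose comparison), or as a reference implementation to
validate faster engines against.  Everything runs from Python on one CPU;
a thin `ccdose` CLI covers the shell-level workflow.

## The algorithm

Dose is computed in the classic three S/C steps:

1. **Fluence** Ψ_E(u, v): a two-source treatment-head model — a primary
   point source with a 16-bin spectrum and arbitrary radial intensity
   profile, plus a Gaussian extrafocal (head-scatter) source that is
   partially obscured by small apertures — transported through jaws and
   MLC (rounded leaf ends, tongue-and-groove strips), with an electron
   contamination channel carried separately.
2. **TERMA** T(r): per voxel and energy bin,
   `T += Ψ_b · (μ/ρ)_b · E_b · exp(−(μ/ρ)_w,b · d_we) · (SAD/r)²`, where
   d_we is the exact voxel-traversal (Siddon-style) radiological path.
   Bin-wise attenuation of the spectrum is the beam-hardening mechanism.
3. **Superposition** D(r): the water point kernel h(θ, r), tabulated at
   1 mm/1° and discretized into collapsed cones, spreads TERMA with the
   kernel argument equal to the *radiological* distance (density-scaled
   superposition, not plain convolution).  A cumulative-cumulative kernel
   (CCK) gives exact bin-averaged deposition per voxel-sized step; cone
   axes optionally tilt to follow local ray divergence; each voxel uses
   the kernel nearest its recorded mean interacting-photon energy.

Arcs accumulate TERMA every 2° of gantry and superpose every 5°; MU is
conserved exactly.  An optional, deliberately nonphysical
heterogeneity-compensated superposition (HCS) mode filters the density
near interfaces (superposition only; off by default).

Beam data (6 MV, 10 MV FFF, 15 MV spectra/profiles, nine-material
radiological table, point kernels) are self-authored surrogates shipped as
YAML; see `docs/methods.md` for their exact construction and the engine's
numerical choices.

## Worked example

Depth dose in water for the three surrogate energies
(`python examples/water_pdd.py`):

```
energy   d_max   PDD(10 cm)  PDD(20 cm)  surface
6MV     18.0 mm     63.6%       31.1%     58.6%
10FFF   23.0 mm     69.3%       36.6%     46.9%
15MV    29.0 mm     75.8%       44.5%     32.8%
```

The depth of maximum dose deepens and the percentage depth dose at 10 cm
rises with beam energy — harder spectra penetrate further and push the
electron build-up region deeper — while surface dose falls.  These are the
classic commissioning-style sanity checks for a photon dose engine.

Other examples: `slab_lung_hcs.py` (small-field lung-slab depth dose with
and without HCS), `gamma_comparison.py` (3%G/2 mm vs 2%G/2 mm gamma
reporting), `five_beam_thorax.py` (conformal five-beam plan on the thorax
phantom with an ion-chamber-style ROI mean).

CLI equivalents:

```
ccdose phantom --kind slab_lung --spacing 2.5 --out slab.ccd
ccdose calc --beam 6MV --plan plan.json --ct slab.ccd --out dose.ccd
ccdose gamma --ref a.ccd --eval b.ccd --dose-pct 3 --dta-mm 2
```

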