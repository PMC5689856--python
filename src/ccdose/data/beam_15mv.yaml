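name: 15MV surrogate
version: 1
sad_mm: 1000.0
primary_spectrum:
  bin_energies_mev:
  - 0.25
  - 0.5
  - 0.75
  - 1.0
  - 1.25
  - 1.5
  - 2.0
  - 2.5
  - 3.0
  - 4.0
  - 5.0
  - 6.0
  - 8.0
  - 10.0
  - 12.0
  - 15.0
  bin_weights:
  - 0.019613
  - 0.036278
  - 0.050327
  - 0.06206
  - 0.071745
  - 0.079624
  - 0.090808
  - 0.097091
  - 0.099655
  - 0.097213
  - 0.088903
  - 0.078051
  - 0.055704
  - 0.03727
  - 0.023939
  - 0.011718
extrafocal_spectrum:
  bin_energies_mev:
  - 0.25
  - 0.5
  - 0.75
  - 1.0
  - 1.25
  - 1.5
  - 2.0
  - 2.5
  - 3.0
  - 4.0
  - 5.0
  - 6.0
  - 8.0
  - 10.0
  - 12.0
  - 15.0
  bin_weights:
  - 0.046986
  - 0.065866
  - 0.077694
  - 0.085393
  - 0.09029
  - 0.093157
  - 0.094694
  - 0.0926
  - 0.088361
  - 0.076826
  - 0.064259
  - 0.052448
  - 0.033362
  - 0.020416
  - 0.012191
  - 0.005458
primary_radial_profile:
  radius_mm:
  - 0.0
  - 200.0
  intensity:
  - 1.0
  - 1.0
extrafocal_fraction: 0.05
extrafocal_source_width_mm: 2.0
extrafocal_distance_mm: 125.0
contamination:
  amplitude: 0.04
  depth_constant_mm: 15.0
mlc:
  leaf_widths_mm:
  - 10.0
  - 10.0
  - 10.0
  - 10.0
  - 10.0
  - 10.0
  - 10.0
  - 10.0
  - 10.0
  - 10.0
  - 10.0
  - 10.0
  - 10.0
  - 10.0
  - 10.0
  - 10.0
  - 10.0
  - 10.0
  - 10.0
  - 10.0
  - 10.0
  - 10.0
  - 10.0
  - 10.0
  - 10.0
  - 10.0
  - 10.0
  - 10.0
  - 10.0
  - 10.0
  - 10.0
  - 10.0
  - 10.0
  - 10.0
  - 10.0
  - 10.0
  - 10.0
  - 10.0
  - 10.0
  - 10.0
  transmission: 0.015
  leaf_end_radius_mm: 80.0
  leaf_height_mm: 70.0
  tongue_groove_width_mm: 1.0
jaw_transmission: 0.002
calibration:
  dose_per_mu_gy: 0.008
  ref_field_cm: 10.0
  ref_depth_mm: 100.0
  ref_ssd_mm: 900.0
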