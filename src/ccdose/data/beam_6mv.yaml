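name: 6MV surrogate
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
  - 0.065388
  - 0.104189
  - 0.124512
  - 0.132266
  - 0.131721
  - 0.125931
  - 0.106577
  - 0.08456
  - 0.064408
  - 0.034599
  - 0.017425
  - 0.008424
  - 0.0
  - 0.0
  - 0.0
  - 0.0
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
  - 0.117993
  - 0.142485
  - 0.144784
  - 0.137082
  - 0.12486
  - 0.110976
  - 0.083712
  - 0.060747
  - 0.043016
  - 0.020596
  - 0.009487
  - 0.004264
  - 0.0
  - 0.0
  - 0.0
  - 0.0
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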