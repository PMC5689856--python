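name: 10FFF surrogate
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
  - 0.050864
  - 0.07764
  - 0.094149
  - 0.103902
  - 0.108895
  - 0.110461
  - 0.106874
  - 0.0982
  - 0.087331
  - 0.064945
  - 0.045866
  - 0.031352
  - 0.013774
  - 0.005747
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
  - 0.100136
  - 0.11584
  - 0.11944
  - 0.117485
  - 0.112617
  - 0.106201
  - 0.091584
  - 0.076965
  - 0.063632
  - 0.042177
  - 0.027244
  - 0.017313
  - 0.006779
  - 0.002587
  - 0.0
  - 0.0
primary_radial_profile:
  radius_mm:
  - 0.0
  - 30.0
  - 60.0
  - 100.0
  - 150.0
  - 200.0
  intensity:
  - 1.0
  - 0.97
  - 0.9
  - 0.8
  - 0.68
  - 0.55
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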