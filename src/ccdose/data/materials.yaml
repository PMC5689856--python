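version: 1
note: Surrogate nine-material radiological property table (water anchored to standard
  published photon cross-section compilations; other materials scaled).
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
materials:
- name: air
  reference_ed: 0.001
  mu_over_rho:
  - 0.124015
  - 0.09529
  - 0.079759
  - 0.069765
  - 0.062433
  - 0.056853
  - 0.048914
  - 0.043417
  - 0.039388
  - 0.03378
  - 0.030137
  - 0.027576
  - 0.024225
  - 0.022156
  - 0.020726
  - 0.0191
  muen_over_rho:
  - 0.030273
  - 0.032452
  - 0.031805
  - 0.030491
  - 0.029241
  - 0.027982
  - 0.025744
  - 0.023917
  - 0.022522
  - 0.020368
  - 0.018898
  - 0.017919
  - 0.016449
  - 0.015469
  - 0.014885
  - 0.0142
- name: lung_surrogate
  reference_ed: 0.26
  mu_over_rho:
  - 0.125281
  - 0.096095
  - 0.080352
  - 0.070232
  - 0.062816
  - 0.057177
  - 0.049157
  - 0.043609
  - 0.039544
  - 0.03389
  - 0.030219
  - 0.027638
  - 0.024263
  - 0.022178
  - 0.020737
  - 0.0191
  muen_over_rho:
  - 0.030582
  - 0.032726
  - 0.032042
  - 0.030696
  - 0.02942
  - 0.028141
  - 0.025872
  - 0.024023
  - 0.022611
  - 0.020434
  - 0.018949
  - 0.01796
  - 0.016475
  - 0.015485
  - 0.014893
  - 0.0142
- name: adipose
  reference_ed: 0.95
  mu_over_rho:
  - 0.124015
  - 0.095126
  - 0.079542
  - 0.069525
  - 0.062184
  - 0.056602
  - 0.048663
  - 0.043171
  - 0.039147
  - 0.03355
  - 0.029916
  - 0.027361
  - 0.02402
  - 0.021956
  - 0.020529
  - 0.018909
  muen_over_rho:
  - 0.030273
  - 0.032396
  - 0.031719
  - 0.030387
  - 0.029124
  - 0.027858
  - 0.025612
  - 0.023782
  - 0.022384
  - 0.020229
  - 0.018759
  - 0.01778
  - 0.01631
  - 0.01533
  - 0.014744
  - 0.014058
- name: water
  reference_ed: 1.0
  mu_over_rho:
  - 0.126546
  - 0.0969
  - 0.080944
  - 0.0707
  - 0.0632
  - 0.0575
  - 0.0494
  - 0.043801
  - 0.0397
  - 0.034
  - 0.0303
  - 0.0277
  - 0.0243
  - 0.0222
  - 0.020748
  - 0.0191
  muen_over_rho:
  - 0.030891
  - 0.033
  - 0.032278
  - 0.0309
  - 0.0296
  - 0.0283
  - 0.026
  - 0.024129
  - 0.0227
  - 0.0205
  - 0.019
  - 0.018
  - 0.0165
  - 0.0155
  - 0.014901
  - 0.0142
- name: muscle
  reference_ed: 1.04
  mu_over_rho:
  - 0.126546
  - 0.0969
  - 0.080944
  - 0.0707
  - 0.0632
  - 0.0575
  - 0.0494
  - 0.043801
  - 0.0397
  - 0.034
  - 0.0303
  - 0.0277
  - 0.0243
  - 0.0222
  - 0.020748
  - 0.0191
  muen_over_rho:
  - 0.030891
  - 0.033
  - 0.032278
  - 0.0309
  - 0.0296
  - 0.0283
  - 0.026
  - 0.024129
  - 0.0227
  - 0.0205
  - 0.019
  - 0.018
  - 0.0165
  - 0.0155
  - 0.014901
  - 0.0142
- name: cartilage
  reference_ed: 1.1
  mu_over_rho:
  - 0.127812
  - 0.097869
  - 0.081753
  - 0.071407
  - 0.063832
  - 0.058075
  - 0.049894
  - 0.044239
  - 0.040097
  - 0.03434
  - 0.030603
  - 0.027977
  - 0.024543
  - 0.022422
  - 0.020956
  - 0.019291
  muen_over_rho:
  - 0.0312
  - 0.03333
  - 0.032601
  - 0.031209
  - 0.029896
  - 0.028583
  - 0.02626
  - 0.02437
  - 0.022927
  - 0.020705
  - 0.01919
  - 0.01818
  - 0.016665
  - 0.015655
  - 0.01505
  - 0.014342
- name: trabecular_bone
  reference_ed: 1.18
  mu_over_rho:
  - 0.132874
  - 0.101581
  - 0.084774
  - 0.073996
  - 0.066112
  - 0.060123
  - 0.051619
  - 0.045744
  - 0.041444
  - 0.03547
  - 0.031593
  - 0.02887
  - 0.025309
  - 0.02311
  - 0.021589
  - 0.019864
  muen_over_rho:
  - 0.032436
  - 0.034594
  - 0.033805
  - 0.03234
  - 0.030964
  - 0.029591
  - 0.027168
  - 0.025199
  - 0.023697
  - 0.021386
  - 0.019811
  - 0.01876
  - 0.017185
  - 0.016135
  - 0.015506
  - 0.014768
- name: cortical_bone
  reference_ed: 1.7
  mu_over_rho:
  - 0.144263
  - 0.10981
  - 0.091407
  - 0.07964
  - 0.071054
  - 0.064543
  - 0.055312
  - 0.048947
  - 0.044294
  - 0.037839
  - 0.033655
  - 0.030718
  - 0.026879
  - 0.024508
  - 0.022868
  - 0.02101
  muen_over_rho:
  - 0.035216
  - 0.037397
  - 0.03645
  - 0.034808
  - 0.033279
  - 0.031767
  - 0.029112
  - 0.026964
  - 0.025327
  - 0.022815
  - 0.021104
  - 0.019961
  - 0.018251
  - 0.017111
  - 0.016424
  - 0.01562
- name: metal_surrogate
  reference_ed: 4.0
  mu_over_rho:
  - 0.202474
  - 0.152579
  - 0.126252
  - 0.109529
  - 0.097394
  - 0.088226
  - 0.075277
  - 0.066386
  - 0.059906
  - 0.050946
  - 0.045155
  - 0.041095
  - 0.035795
  - 0.03252
  - 0.030255
  - 0.027695
  muen_over_rho:
  - 0.049426
  - 0.051962
  - 0.050345
  - 0.047871
  - 0.045615
  - 0.043422
  - 0.039619
  - 0.03657
  - 0.034253
  - 0.030718
  - 0.028315
  - 0.026704
  - 0.024305
  - 0.022705
  - 0.021729
  - 0.02059
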