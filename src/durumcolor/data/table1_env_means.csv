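environment,trait,mean,sd
ENV1,HP,2.207,1.814
ENV1,BL,0.007,0.004
ENV1,POD,88.085,53.558
ENV1,PPO,150.317,91.262
ENV1,LUT_S,1.939,0.627
ENV1,BCAR_S,0.524,0.239
ENV1,YI_S,23.687,2.818
ENV1,BI_S,14.894,0.767
ENV1,LUT_P,0.257,0.108
ENV1,BCAR_P,0.091,0.065
ENV1,YI_P,19.711,1.39
ENV1,BI_P,16.061,0.854
ENV2,HP,2.536,2.342
ENV2,BL,0.004,0.003
ENV2,POD,63.798,44.962
ENV2,PPO,143.255,95.172
ENV2,LUT_S,1.584,0.537
ENV2,BCAR_S,0.501,0.235
ENV2,YI_S,22.418,3.144
ENV2,BI_S,13.928,0.541
ENV2,LUT_P,0.186,0.079
ENV2,BCAR_P,0.071,0.039
ENV2,YI_P,18.333,2.457
ENV2,BI_P,15.067,0.635
ENV3,HP,2.021,2.121
ENV3,BL,0.009,0.009
ENV3,POD,76.794,51.64
ENV3,PPO,230.835,166.08
ENV3,LUT_S,1.578,0.632
ENV3,BCAR_S,0.504,0.265
ENV3,YI_S,22.737,3.093
ENV3,BI_S,14.078,0.705
ENV3,LUT_P,0.159,0.068
ENV3,BCAR_P,0.059,0.030
ENV3,YI_P,18.944,2.372
ENV3,BI_P,14.989,0.810
ENV4,HP,1.780,1.622
ENV4,BL,0.003,0.004
ENV4,POD,74.848,50.823
ENV4,PPO,175.371,127.671
ENV4,LUT_S,2.258,0.784
ENV4,BCAR_S,0.533,0.286
ENV4,YI_S,23.518,2.993
ENV4,BI_S,12.744,0.630
ENV4,LUT_P,0.265,0.079
ENV4,BCAR_P,0.060,0.031
ENV4,YI_P,20.228,2.512
ENV4,BI_P,13.806,0.569
ENV5,HP,1.722,1.604
ENV5,BL,0.003,0.003
ENV5,POD,60.804,41.421
ENV5,PPO,132.449,68.127
ENV5,LUT_S,2.223,0.759
ENV5,BCAR_S,0.497,0.252
ENV5,YI_S,23.304,3.334
ENV5,BI_S,13.072,0.604
ENV5,LUT_P,0.344,0.259
ENV5,BCAR_P,0.082,0.088
ENV5,YI_P,20.017,2.651
ENV5,BI_P,14.106,0.644
ENV6,HP,1.589,1.312
ENV6,BL,0.006,0.004
ENV6,POD,90.043,62.742
ENV6,PPO,208.868,104.753
ENV6,LUT_S,1.902,0.700
ENV6,BCAR_S,0.520,0.282
ENV6,YI_S,22.942,3.145
ENV6,BI_S,13.217,0.637
ENV6,LUT_P,0.218,0.081
ENV6,BCAR_P,0.052,0.035
ENV6,YI_P,19.389,2.692
ENV6,BI_P,14.361,0.730
ENV7,HP,1.329,1.171
ENV7,BL,0.007,0.006
ENV7,POD,106.996,66.394
ENV7,PPO,217.845,142.554
ENV7,LUT_S,1.892,0.692
ENV7,BCAR_S,0.491,0.207
ENV7,YI_S,24.833,2.831
ENV7,BI_S,15.406,0.665
ENV7,LUT_P,0.169,0.083
ENV7,BCAR_P,0.034,0.024
ENV7,YI_P,20.511,2.305
ENV7,BI_P,16.761,0.787
ENV8,HP,1.564,1.255
ENV8,BL,0.005,0.005
ENV8,POD,138.508,84.528
ENV8,PPO,228.261,158.994
ENV8,LUT_S,0.941,0.517
ENV8,BCAR_S,0.148,0.072
ENV8,YI_S,23.146,2.790
ENV8,BI_S,12.878,0.701
ENV8,LUT_P,0.180,0.059
ENV8,BCAR_P,0.029,0.018
ENV8,YI_P,19.261,2.055
ENV8,BI_P,14.070,0.739
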