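genotype,trait,mean,sd
Arcobaleno,HP,1.284,0.427
Arcobaleno,BL,0.006,0.003
Arcobaleno,POD,154.492,45.203
Arcobaleno,PPO,273.034,113.304
Arcobaleno,LUT_S,1.718,0.675
Arcobaleno,BCAR_S,0.485,0.164
Arcobaleno,YI_S,23.438,0.748
Arcobaleno,BI_S,14.113,1.201
Arcobaleno,LUT_P,0.165,0.054
Arcobaleno,BCAR_P,0.047,0.018
Arcobaleno,YI_P,19.425,1.054
Arcobaleno,BI_P,15.438,1.337
Claudio,HP,1.442,0.471
Claudio,BL,0.010,0.007
Claudio,POD,118.625,36.392
Claudio,PPO,207.330,51.962
Claudio,LUT_S,2.148,0.607
Claudio,BCAR_S,0.560,0.16
Claudio,YI_S,22.759,0.993
Claudio,BI_S,13.500,0.994
Claudio,LUT_P,0.181,0.06
Claudio,BCAR_P,0.054,0.026
Claudio,YI_P,18.450,0.978
Claudio,BI_P,14.638,1.116
Colosseo,HP,0.937,0.419
Colosseo,BL,0.005,0.002
Colosseo,POD,138.693,39.417
Colosseo,PPO,140.928,46.412
Colosseo,LUT_S,1.031,0.247
Colosseo,BCAR_S,0.210,0.211
Colosseo,YI_S,19.783,0.928
Colosseo,BI_S,13.213,0.888
Colosseo,LUT_P,0.259,0.085
Colosseo,BCAR_P,0.039,0.017
Colosseo,YI_P,17.775,0.517
Colosseo,BI_P,14.125,0.747
Creso,HP,0.671,0.428
Creso,BL,0.005,0.005
Creso,POD,131.700,40.375
Creso,PPO,256.388,63.158
Creso,LUT_S,1.117,0.229
Creso,BCAR_S,0.177,0.037
Creso,YI_S,18.688,1.174
Creso,BI_S,13.875,1.184
Creso,LUT_P,0.124,0.043
Creso,BCAR_P,0.047,0.018
Creso,YI_P,16.525,1.323
Creso,BI_P,14.838,1.163
Duilio,HP,4.640,1.610
Duilio,BL,0.004,0.003
Duilio,POD,15.030,10.055
Duilio,PPO,60.240,31.166
Duilio,LUT_S,1.092,0.309
Duilio,BCAR_S,0.339,0.094
Duilio,YI_S,21.753,0.924
Duilio,BI_S,13.413,1.313
Duilio,LUT_P,0.148,0.024
Duilio,BCAR_P,0.044,0.015
Duilio,YI_P,18.450,1.006
Duilio,BI_P,14.613,1.237
Dupri,HP,0.921,0.277
Dupri,BL,0.007,0.004
Dupri,POD,8.291,3.496
Dupri,PPO,64.113,22.515
Dupri,LUT_S,2.946,0.716
Dupri,BCAR_S,0.745,0.227
Dupri,YI_S,26.324,1.034
Dupri,BI_S,13.775,0.905
Dupri,LUT_P,0.204,0.041
Dupri,BCAR_P,0.068,0.038
Dupri,YI_P,21.400,1.143
Dupri,BI_P,14.788,0.926
Flaminio,HP,0.970,0.252
Flaminio,BL,0.001,0.001
Flaminio,POD,17.086,5.515
Flaminio,PPO,84.943,38.013
Flaminio,LUT_S,2.336,0.495
Flaminio,BCAR_S,0.652,0.184
Flaminio,YI_S,25.441,0.672
Flaminio,BI_S,13.450,1.250
Flaminio,LUT_P,0.219,0.060
Flaminio,BCAR_P,0.046,0.016
Flaminio,YI_P,21.200,1.089
Flaminio,BI_P,14.471,1.212
Gianni,HP,0.870,0.151
Gianni,BL,0.004,0.002
Gianni,POD,9.318,4.214
Gianni,PPO,61.018,28.986
Gianni,LUT_S,1.084,0.202
Gianni,BCAR_S,0.170,0.043
Gianni,YI_S,18.709,0.893
Gianni,BI_S,12.925,0.994
Gianni,LUT_P,0.135,0.025
Gianni,BCAR_P,0.024,0.014
Gianni,YI_P,16.338,1.081
Gianni,BI_P,14.000,1.068
Iride,HP,1.052,0.267
Iride,BL,0.007,0.003
Iride,POD,106.818,30.023
Iride,PPO,137.060,54.426
Iride,LUT_S,1.844,0.351
Iride,BCAR_S,0.361,0.074
Iride,YI_S,22.889,1.018
Iride,BI_S,13.838,1.034
Iride,LUT_P,0.181,0.036
Iride,BCAR_P,0.027,0.017
Iride,YI_P,19.063,1.068
Iride,BI_P,14.825,1.193
Meridiano,HP,1.312,0.281
Meridiano,BL,0.001,0.003
Meridiano,POD,110.448,37.772
Meridiano,PPO,227.706,69.657
Meridiano,LUT_S,2.621,0.658
Meridiano,BCAR_S,0.776,0.215
Meridiano,YI_S,25.670,1.290
Meridiano,BI_S,14.225,1.004
Meridiano,LUT_P,0.416,0.250
Meridiano,BCAR_P,0.157,0.092
Meridiano,YI_P,21.088,1.339
Meridiano,BI_P,15.288,1.244
Nefer,HP,0.967,0.331
Nefer,BL,0.020,0.008
Nefer,POD,142.755,33.476
Nefer,PPO,268.312,88.313
Nefer,LUT_S,1.376,0.481
Nefer,BCAR_S,0.344,0.095
Nefer,YI_S,23.761,0.739
Nefer,BI_S,14.188,0.793
Nefer,LUT_P,0.236,0.086
Nefer,BCAR_P,0.045,0.023
Nefer,YI_P,20.263,0.826
Nefer,BI_P,15.150,0.956
Parsifal,HP,0.509,0.217
Parsifal,BL,0.004,0.002
Parsifal,POD,26.010,23.127
Parsifal,PPO,96.948,46.591
Parsifal,LUT_S,1.695,0.297
Parsifal,BCAR_S,0.379,0.025
Parsifal,YI_S,20.867,0.772
Parsifal,BI_S,12.788,0.967
Parsifal,LUT_P,0.192,0.078
Parsifal,BCAR_P,0.036,0.016
Parsifal,YI_P,17.850,0.621
Parsifal,BI_P,14.050,1.087
Preco,HP,5.056,0.861
Preco,BL,0.002,0.002
Preco,POD,34.454,10.969
Preco,PPO,78.097,35.682
Preco,LUT_S,2.952,1.002
Preco,BCAR_S,0.923,0.339
Preco,YI_S,31.482,0.708
Preco,BI_S,14.300,1.181
Preco,LUT_P,0.464,0.247
Preco,BCAR_P,0.145,0.077
Preco,YI_P,25.925,2.177
Preco,BI_P,15.425,1.257
Saadi,HP,0.411,0.231
Saadi,BL,0.005,0.003
Saadi,POD,137.448,48.702
Saadi,PPO,171.027,41.246
Saadi,LUT_S,1.811,0.411
Saadi,BCAR_S,0.473,0.120
Saadi,YI_S,22.777,0.794
Saadi,BI_S,14.000,0.945
Saadi,LUT_P,0.160,0.071
Saadi,BCAR_P,0.055,0.031
Saadi,YI_P,19.213,1.084
Saadi,BI_P,15.275,1.056
San Carlo,HP,1.655,0.665
San Carlo,BL,0.006,0.006
San Carlo,POD,107.216,42.485
San Carlo,PPO,285.593,126.047
San Carlo,LUT_S,1.809,0.452
San Carlo,BCAR_S,0.705,0.243
San Carlo,YI_S,24.445,0.783
San Carlo,BI_S,13.900,0.892
San Carlo,LUT_P,0.204,0.048
San Carlo,BCAR_P,0.049,0.02
San Carlo,YI_P,20.350,1.471
San Carlo,BI_P,15.238,0.994
Simeto,HP,4.062,1.547
Simeto,BL,0.007,0.004
Simeto,POD,167.517,30.868
Simeto,PPO,494.108,146.923
Simeto,LUT_S,1.711,0.359
Simeto,BCAR_S,0.319,0.071
Simeto,YI_S,23.013,1.054
Simeto,BI_S,14.575,1.057
Simeto,LUT_P,0.222,0.075
Simeto,BCAR_P,0.038,0.02
Simeto,YI_P,19.388,1.411
Simeto,BI_P,15.438,1.056
Torrebianca,HP,4.898,1.315
Torrebianca,BL,0.005,0.003
Torrebianca,POD,97.698,34.32
Torrebianca,PPO,246.375,57.289
Torrebianca,LUT_S,1.567,0.396
Torrebianca,BCAR_S,0.339,0.095
Torrebianca,YI_S,22.989,0.706
Torrebianca,BI_S,14.200,0.919
Torrebianca,LUT_P,0.221,0.070
Torrebianca,BCAR_P,0.042,0.014
Torrebianca,YI_P,18.625,0.506
Torrebianca,BI_P,14.863,1.308
Verdi,HP,1.524,1.230
Verdi,BL,0.005,0.002
Verdi,POD,51.122,17.611
Verdi,PPO,192.983,46.37
Verdi,LUT_S,1.356,0.388
Verdi,BCAR_S,0.408,0.132
Verdi,YI_S,25.033,1.343
Verdi,BI_S,13.713,1.088
Verdi,LUT_P,0.273,0.076
Verdi,BCAR_P,0.110,0.030
Verdi,YI_P,20.563,1.438
Verdi,BI_P,15.788,1.183
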