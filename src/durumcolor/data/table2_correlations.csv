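trait_1,trait_2,r,p
BL,HP,-0.10,0.239
POD,HP,-0.12,0.165
POD,BL,0.34,0.000
PPO,HP,0.09,0.265
PPO,BL,0.37,0.000
PPO,POD,0.71,0.000
LUT_S,HP,0.05,0.585
LUT_S,BL,-0.23,0.006
LUT_S,POD,-0.27,0.001
LUT_S,PPO,-0.20,0.019
BCAR_S,HP,0.13,0.118
BCAR_S,BL,-0.18,0.033
BCAR_S,POD,-0.30,0.000
BCAR_S,PPO,-0.17,0.036
BCAR_S,LUT_S,0.86,0.000
YI_S,HP,0.30,0.000
YI_S,BL,-0.07,0.389
YI_S,POD,-0.14,0.085
YI_S,PPO,-0.06,0.513
YI_S,LUT_S,0.66,0.000
YI_S,BCAR_S,0.71,0.000
BI_S,HP,0.19,0.022
BI_S,BL,0.32,0.000
BI_S,POD,0.24,0.003
BI_S,PPO,0.28,0.001
BI_S,LUT_S,0.09,0.261
BI_S,BCAR_S,0.23,0.007
BI_S,YI_S,0.33,0.000
LUT_P,HP,0.19,0.019
LUT_P,BL,-0.23,0.006
LUT_P,POD,-0.12,0.147
LUT_P,PPO,-0.10,0.246
LUT_P,LUT_S,0.50,0.000
LUT_P,BCAR_S,0.43,0.000
LUT_P,YI_S,0.50,0.000
LUT_P,BI_S,-0.03,0.681
BCAR_P,HP,0.19,0.026
BCAR_P,BL,-0.21,0.013
BCAR_P,POD,-0.19,0.022
BCAR_P,PPO,-0.14,0.091
BCAR_P,LUT_S,0.50,0.000
BCAR_P,BCAR_S,0.57,0.000
BCAR_P,YI_S,0.50,0.000
BCAR_P,BI_S,0.16,0.052
BCAR_P,LUT_P,0.80,0.000
BI_P,HP,0.10,0.229
BI_P,BL,0.26,0.002
BI_P,POD,0.21,0.013
BI_P,PPO,0.21,0.010
BI_P,LUT_S,0.06,0.440
BI_P,BCAR_S,0.22,0.009
BI_P,YI_S,0.35,0.000
BI_P,BI_S,0.93,0.000
BI_P,LUT_P,-0.04,0.635
BI_P,BCAR_P,0.19,0.026
YI_P,HP,0.26,0.002
YI_P,BL,-0.08,0.354
YI_P,POD,-0.14,0.095
YI_P,PPO,-0.09,0.286
YI_P,LUT_S,0.64,0.000
YI_P,BCAR_S,0.66,0.000
YI_P,YI_S,0.93,0.000
YI_P,BI_S,0.21,0.012
YI_P,LUT_P,0.53,0.000
YI_P,BCAR_P,0.45,0.000
YI_P,BI_P,0.23,0.005
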