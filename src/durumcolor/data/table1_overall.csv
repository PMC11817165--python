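trait,mean,sd
HP,1.843,1.726
BL,0.006,0.006
POD,87.485,62.699
PPO,185.9,128.421
LUT_S,1.79,0.768
BCAR_S,0.465,0.266
YI_S,23.323,3.077
BI_S,13.777,1.126
LUT_P,0.222,0.132
BCAR_P,0.06,0.05
YI_P,19.549,2.414
BI_P,14.903,1.216
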