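environment,HP,BL,POD,PPO,LUT_S,BCAR_S,YI_S,BI_S,LUT_P,BCAR_P,YI_P,BI_P,HPI
ENV3,7.03,4.93,-0.03,2.00,-0.48,-0.35,-0.23,-0.20,-0.90,-0.58,-0.20,-0.2,10.80
ENV4,4.83,6.13,0.12,1.73,-0.20,-0.63,-0.23,-0.23,-0.23,-0.78,-0.18,-0.25,10.10
ENV7,4.38,3.78,-0.08,1.75,-0.20,-0.20,-0.18,-0.23,-0.70,-1.68,-0.23,-0.25,6.17
ENV2,4.75,2.63,0.60,1.88,-0.30,-0.28,-0.20,-0.18,-1.08,-1.50,-0.20,-0.2,5.92
ENV8,3.38,5.00,-0.23,1.30,-1.15,-1.10,-0.20,-0.28,-0.25,-1.13,-0.30,-0.175,4.88
ENV6,3.30,1.95,-0.08,0.02,-0.23,-1.05,-0.18,-0.23,-0.25,-2.35,-0.18,-0.275,0.47
ENV1,2.98,0.33,-0.20,1.38,-0.18,-0.23,-0.23,-0.23,-0.55,-2.88,-0.20,-0.25,-0.25
ENV5,4.55,3.78,0.18,-0.15,-0.25,-0.30,-0.23,-0.25,-4.23,-7.53,-0.23,-0.225,-4.88
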