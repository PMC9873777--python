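top_cm,bottom_cm,bd,dul,cll,sw,kl
0,15,1.22,0.27,0.08,0.23,0.08
15,30,1.20,0.26,0.12,0.23,0.07
30,45,1.07,0.25,0.11,0.24,0.06
45,60,1.03,0.24,0.13,0.24,0.05
60,75,1.10,0.28,0.11,0.27,0.04
75,90,1.13,0.30,0.13,0.30,0.03
90,105,0.99,0.26,0.14,0.26,0.02
105,120,1.01,0.27,0.17,0.27,0.02
120,140,1.11,0.31,0.20,0.31,0.02
140,160,1.03,0.28,0.15,0.28,0.02
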