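top_cm,bottom_cm,bd,dul,cll,sw,kl
0,15,1.13,0.39,0.08,0.36,0.08
15,30,1.11,0.48,0.17,0.35,0.07
30,60,1.21,0.50,0.22,0.33,0.06
60,90,1.22,0.53,0.24,0.31,0.05
90,120,1.24,0.48,0.26,0.32,0.04
120,150,1.25,0.51,0.23,0.31,0.03
150,180,1.21,0.52,0.22,0.29,0.02
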