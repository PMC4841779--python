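domain,tau_invivo_min,tau_invivo_sem,n_replicates,invivo_behavior,D_um2_s,tau_fw_min,tau_fw_sem,fw_poor_fit
SHIP2,0.55,0.15,3,recovery,0.040,1.13,0.81,True
SHP2-N,0.91,0.02,2,recovery,0.187,0.60,0.01,False
GRB14,0.99,0.47,2,recovery,,-1.50,0.08,False
SHP2-NC,1.57,0.18,5,recovery,0.081,1.57,0.18,False
SHP2-C,1.85,0.49,8,recovery,0.759,,,False
EAT2,2.26,1.10,2,recovery,0.097,0.64,0.51,True
PLCg1-NC,2.44,0.18,2,recovery,0.022,0.62,0.19,False
p85a-NC,3.06,0.32,2,recovery,0.004,0.51,0.09,False
SHC-PTB,3.25,0.08,4,recovery,0.007,0.69,0.08,False
GRB7,3.45,0.67,3,recovery,0.009,0.77,0.05,False
VAV2,4.27,0.52,2,recovery,0.034,0.80,0.17,False
SHC-SH2,4.57,0.20,4,recovery,0.026,,,False
GRB2,4.58,0.41,11,recovery,0.021,0.59,0.03,False
PLCg1-N,5.15,2.28,2,recovery,0.022,0.75,0.33,False
CRK,5.54,0.64,2,recovery,0.016,-2.80,0.29,False
RASGAP-NC,5.92,0.80,2,recovery,0.076,-1.27,0.54,True
PLCg1-C,6.48,1.27,5,recovery,0.043,0.30,0.03,False
ARG,6.55,0.90,2,recovery,0.010,0.54,0.20,False
p85a-N,6.88,0.78,2,recovery,0.016,0.67,0.10,False
RASGAP-N,6.99,2.53,2,recovery,0.011,-2.51,0.98,False
FYN,,,2,constant,0.008,0.43,0.04,False
NCK1,,,2,decrease,0.009,-0.83,0.03,False
RASGAP-C,,,2,constant,,1.27,0.54,True
ABL,,,3,constant,,0.70,0.40,False
YES,,,,nd,,-3.62,1.48,True
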