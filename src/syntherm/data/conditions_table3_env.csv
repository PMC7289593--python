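species,activity,unit
HCO3-,2.020e-02,M
CH4,3.000e-05,M
SO4-2,5.200e-03,M
H2S,8.000e-04,M
Fe+2,3.000e-05,M
NO3-,1.850e-04,M
NO2-,1.160e-05,M
PCE,3.190e-07,M
TCE,7.290e-07,M
Cl-,1.690e-02,M
acetate-,1.000e-04,M
cDCE,4.570e-07,M
DCA,4.730e-07,M
ethene,1.340e-03,M
2-CP,5.072e-07,M
phenol,2.178e-06,M
MCB,5.313e-07,M
benzene,7.105e-07,M
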