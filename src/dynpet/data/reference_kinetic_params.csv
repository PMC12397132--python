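structure,K1,k2,k3,vb,ki_2tcm,ki_patlak,vb_patlak
tumor_border,0.08,0.18,0.08,0.07,0.03,0.02,0.22
tumor_center,0.05,0.19,0.06,0.05,0.01,0.01,0.17
liver,0.1,0.34,0.04,0.33,0.011,0.007,0.468
lungs,0.017,0.3,0.027,0.067,0.001,0.001,0.106
bone,0.037,0.22,0.044,0.11,0.006,0.005,0.201
heart,0.11,0.38,0.066,0.17,0.016,0.013,0.3
spleen,0.055,0.28,0.03,0.23,0.005,0.004,0.34
muscle,0.038,0.24,0.018,0.007,0.003,0.003,0.15
fat,0.015,0.29,0.024,0.011,0.001,0.001,0.05
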