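segment,mass_fraction,length_fraction,com_ratio,gyration_ratio_frontal
Trunk,0.333,0.300,0.45,0.33
Pelvis,0.142,0.100,0.50,0.55
P-upperarm,0.024,0.186,0.44,0.29
P-forearm,0.017,0.146,0.43,0.27
P-thigh,0.123,0.245,0.41,0.29
P-shank,0.048,0.246,0.40,0.28
P-foot,0.012,0.152,0.44,0.22
N-upperarm,0.024,0.186,0.44,0.29
N-forearm,0.017,0.146,0.43,0.27
N-thigh,0.123,0.245,0.41,0.29
N-shank,0.048,0.246,0.40,0.28
N-foot,0.012,0.152,0.44,0.22
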