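label,rmsd_A,rg_A,sasa_1e4_A2,n_hbond,rmsd_alphafold_A
WT,2.41,22.24,1.25,59,1.51
aE219G,2.67,22.15,1.26,61,1.51
aE219Q,2.60,22.46,1.30,61,1.49
aH245G,2.36,22.31,1.26,59,1.73
aH245S,2.45,22.40,1.28,59,1.61
aH245Y,2.91,22.44,1.37,61,1.89
aE219H/aH245E,2.51,22.20,1.29,57,1.67
aN214L,2.64,22.34,1.30,61,1.48
aN214H,2.59,22.47,1.32,60,1.43
aQ252L,2.94,22.37,1.32,58,1.48
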