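motif,from,G+,G-,P+T+,P-T-,P+T-,P-T+
C1,G+,0.251,0,0.008,0,0,0
C1,G-,0,0.329,0,0,0.003,0
C1,P+T+,0.015,0,0.180,0.013,0,0
C1,P-T-,0,0,0.015,0.157,0,0
C1,P+T-,0,0.0049,0,0,0.031,0
C1,P-T+,0,0,0,0,0,0
C2,G+,0,0,0.007,0,0,0
C2,G-,0,0.82,0,0,0.007,0
C2,P+T+,0.008,0,0.022,0.001,0,0
C2,P-T-,0,0,0.043,0.039,0,0
C2,P+T-,0,0.007,0,0,0.039,0
C2,P-T+,0,0,0,0,0,0
C3,G+,0.317,0,0.008,0,0,0
C3,G-,0,0.242,0,0,0.026,0
C3,P+T+,0.023,0,0.030,0,0,0
C3,P-T-,0,0,0,0,0,0
C3,P+T-,0,0.043,0,0,0.174,0.046
C3,P-T+,0,0,0,0,0.046,0.151
C4,G+,0.815,0,0.019,0,0,0
C4,G-,0,0,0,0,0.019,0
C4,P+T+,0,0,0.037,0,0,0
C4,P-T-,0,0,0,0,0,0
C4,P+T-,0,0.037,0,0,0.037,0
C4,P-T+,0,0,0,0,0,0.037
I1,G+,0.241,0,0.069,0,0,0
I1,G-,0,0.103,0,0,0,0
I1,P+T+,0,0,0.345,0,0,0
I1,P-T-,0,0,0,0.241,0,0
I1,P+T-,0,0,0,0,0,0
I1,P-T+,0,0,0,0,0,0
I2,G+,0.144,0,0.024,0,0,0
I2,G-,0,0.408,0,0,0.016,0
I2,P+T+,0,0,0.160,0,0,0
I2,P-T-,0,0,0,0.128,0,0
I2,P+T-,0,0.032,0,0,0.080,0
I2,P-T+,0,0,0,0,0,0.008
I3,G+,0.091,0,0,0,0,0
I3,G-,0,0.212,0,0,0.061,0
I3,P+T+,0,0,0,0,0,0
I3,P-T-,0,0,0,0,0,0
I3,P+T-,0,0.121,0,0,0.394,0
I3,P-T+,0,0,0,0,0,0.121
I4,G+,0.398,0,0.008,0,0,0
I4,G-,0,0.141,0,0,0.023,0
I4,P+T+,0,0,0.063,0,0,0
I4,P-T-,0,0,0,0.008,0,0
I4,P+T-,0,0.047,0,0,0.156,0
I4,P-T+,0,0,0,0,0,0.156
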