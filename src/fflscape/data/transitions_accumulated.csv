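motif,from,G+,G-,P+T+,P-T-,P+T-,P-T+
C1,G+,0.212,0,0.082,0.071,0,0
C1,G-,0,0.235,0,0,0.010,0
C1,P+T+,0.035,0,0.113,0.052,0,0
C1,P-T-,0.030,0,0.052,0.082,0,0
C1,P+T-,0,0.020,0,0,0.007,0
C1,P-T+,0,0,0,0,0,0
C2,G+,0.005,0,0.008,0.006,0,0
C2,G-,0,0.822,0,0,0.018,0
C2,P+T+,0.006,0,0.013,0.011,0,0
C2,P-T-,0.008,0,0.014,0.018,0,0
C2,P+T-,0,0.056,0,0,0.016,0
C2,P-T+,0,0,0,0,0,0
C3,G+,0.247,0,0.026,0,0,0
C3,G-,0,0.222,0,0,0.050,0.043
C3,P+T+,0.016,0,0.008,0,0,0
C3,P-T-,0,0,0,0,0,0
C3,P+T-,0,0.100,0,0,0.118,0
C3,P-T+,0,0.086,0,0,0,0.086
C4,G+,0.825,0,0.069,0,0,0
C4,G-,0,0,0,0,0.005,0.005
C4,P+T+,0.042,0,0.011,0,0,0
C4,P-T-,0,0,0,0,0,0
C4,P+T-,0,0.011,0,0,0.011,0
C4,P-T+,0,0.011,0,0,0,0.011
I1,G+,0.171,0,0.114,0.086,0,0
I1,G-,0,0.024,0,0,0,0
I1,P+T+,0.033,0,0.229,0.098,0,0
I1,P-T-,0.024,0,0.098,0.122,0,0
I1,P+T-,0,0,0,0,0,0
I1,P-T+,0,0,0,0,0,0
I2,G+,0.088,0,0.048,0.040,0,0
I2,G-,0,0.398,0,0.007,0.029,0.007
I2,P+T+,0.016,0,0.088,0.040,0,0
I2,P-T-,0.013,0.015,0.040,0.061,0,0
I2,P+T-,0,0.058,0,0,0.037,0
I2,P-T+,0,0.015,0,0,0,0.001
I3,G+,0.024,0,0,0,0,0
I3,G-,0,0.165,0,0,0.098,0.039
I3,P+T+,0,0,0,0,0,0
I3,P-T-,0,0,0,0,0,0
I3,P+T-,0,0.196,0,0,0.353,0
I3,P-T+,0,0.078,0,0,0,0.047
I4,G+,0.401,0,0.033,0.017,0,0
I4,G-,0,0.088,0,0,0.032,0.032
I4,P+T+,0.037,0,0.035,0.005,0,0
I4,P-T-,0.009,0,0.003,0.001,0,0
I4,P+T-,0,0.064,0,0,0.088,0
I4,P-T+,0,0.064,0,0,0,0.088
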