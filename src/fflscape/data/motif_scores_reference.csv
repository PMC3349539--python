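motif,kurtosis,psi,rho
C1,1.631,0.297,0.342
C2,4.142,2.808,0.036
C3,3.042,1.707,0.059
C4,4.835,3.501,0.029
I1,-1.721,0.386,0.263
I2,2.506,1.17,0.087
I3,-2.083,0.748,0.136
I4,3.459,2.123,0.048
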