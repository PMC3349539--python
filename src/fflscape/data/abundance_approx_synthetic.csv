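motif,abundance,source
C1,0.437,ecoli_approx_synthetic
C2,0.047,ecoli_approx_synthetic
C3,0.028,ecoli_approx_synthetic
C4,0.019,ecoli_approx_synthetic
I1,0.355,ecoli_approx_synthetic
I2,0.047,ecoli_approx_synthetic
I3,0.038,ecoli_approx_synthetic
I4,0.029,ecoli_approx_synthetic
C1,0.551,yeast_approx_synthetic
C2,0.038,yeast_approx_synthetic
C3,0.030,yeast_approx_synthetic
C4,0.015,yeast_approx_synthetic
I1,0.271,yeast_approx_synthetic
I2,0.045,yeast_approx_synthetic
I3,0.030,yeast_approx_synthetic
I4,0.020,yeast_approx_synthetic
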