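motif,G+,G-,P+T+,P+T-,P-T-,P-T+
C1,0.4862,0.2111,0.2018,0.03669,0.0642,0
C2,0.0931,0.5349,0.1861,0.09302,0.0931,0
C3,0.2336,0.5514,0.0748,0.09346,0.0374,0.0093
C4,0.5862,0.0689,0.1379,0.13793,0,0.0689
I1,0.3571,0.2143,0.2857,0,0.1429,0
I2,0.1111,0.4167,0.1111,0.2222,0.0648,0.0741
I3,0.2553,0.2766,0,0.2979,0,0.1702
I4,0.4019,0.1402,0.1869,0.1308,0.0748,0.0654
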