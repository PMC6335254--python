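posture,rho
A,0.852
AS,0.809
B,0.855
BS,0.779
C,0.878
CS,0.861
D,0.889
DS,0.856
E,0.923
ES,0.88
LBC,0.692
LSL,0.647
LL,0.511
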