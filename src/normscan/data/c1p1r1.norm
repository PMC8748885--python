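# C1-P1-R1 example (ternary, conventional labels)
BB:DG:B
BN:DN:B
BG:CG:N
NB:DB:N
NN:DN:B
NG:CG:B
GB:DG:N
GN:DG:N
GG:CG:B
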