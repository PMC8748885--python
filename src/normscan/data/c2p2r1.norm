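# C2-P2-R1 example
BB:DG:N
BN:DN:N
BG:CG:B
NB:DG:B
NN:DG:N
NG:CG:B
GB:DN:B
GN:CN:B
GG:CG:B
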