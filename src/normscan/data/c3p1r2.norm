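# C3-P1-R2 example
BB:DG:N
BN:CG:B
BG:DB:B
NB:DG:B
NN:CG:B
NG:CN:B
GB:DN:B
GN:CN:B
GG:CG:B
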