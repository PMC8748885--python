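# C1-P2-R2 example
BB:DG:B
BN:DG:N
BG:DN:N
NB:DN:N
NN:DG:G
NG:CG:N
GB:DN:N
GN:DG:B
GG:CG:B
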