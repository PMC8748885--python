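# C1-P1-R2 example
BB:DN:N
BN:DG:G
BG:CN:B
NB:DG:G
NN:CN:B
NG:DG:N
GB:DG:N
GN:DG:B
GG:CG:B
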