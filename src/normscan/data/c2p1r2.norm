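# C2-P1-R2 example
BB:DN:B
BN:DG:N
BG:CN:B
NB:CG:B
NN:DG:G
NG:CN:B
GB:DG:N
GN:CG:B
GG:CG:B
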