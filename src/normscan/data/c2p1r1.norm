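# C2-P1-R1 example
BB:DN:N
BN:CN:B
BG:CG:B
NB:DG:G
NN:CG:B
NG:CG:B
GB:DG:N
GN:CN:B
GG:CG:B
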