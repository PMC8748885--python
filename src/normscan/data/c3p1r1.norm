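# C3-P1-R1 example
BB:DN:N
BN:CG:B
BG:CG:B
NB:DN:G
NN:CN:B
NG:CG:B
GB:DG:G
GN:CG:B
GG:CN:B
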