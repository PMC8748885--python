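# C2-P2-R2 example
BB:CG:B
BN:DN:B
BG:CN:B
NB:DB:B
NN:CG:B
NG:CN:B
GB:DN:G
GN:CG:B
GG:CG:B
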