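# C1-P2-R1 example
BB:DG:G
BN:DB:B
BG:CG:B
NB:DG:N
NN:DB:B
NG:DG:N
GB:DN:N
GN:DG:G
GG:CG:B
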