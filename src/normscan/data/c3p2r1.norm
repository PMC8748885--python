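# C3-P2-R1 example
BB:DG:B
BN:CG:B
BG:CN:B
NB:DG:B
NN:CG:B
NG:CN:B
GB:DB:B
GN:CG:B
GG:CN:B
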