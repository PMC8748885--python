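# C3-P2-R2 example (golden-ratio fixed-point family)
BB:DG:B
BN:DB:B
BG:CG:B
NB:DB:B
NN:CG:B
NG:CG:B
GB:DG:G
GN:CG:B
GG:CN:B
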