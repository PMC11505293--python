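# Major hubs of the curated PCOS interactome (degree >= 20).
hub	degree
TP53	41
INS	34
IL6	33
ESR1	29
IL1B	29
IGF1	27
TNF	26
ACTB	24
EP300	23
NFKB1	21
PPARG	21
TLR4	20
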