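species	n_genes	unculled_stable	unculled_labile	culled_stable	culled_labile
Dmel	83	53	30	46	22
Agam	94	49	45	31	28
Aaeg	131	58	73	33	30
Cqui	178	85	93	52	35
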