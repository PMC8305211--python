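binding_site	name	consistency_rmsd	n_sulfates	goldscore
1	uAB–VbC4B	2.5	1	53.1
1	VbC6B–Zb2B	2.5	2	56.3
1	ZbB–VbCB	2.5	0	44.2
2	uAB–VbCB	2.3	1	39.2
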