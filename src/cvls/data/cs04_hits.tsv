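binding_site	name	consistency_rmsd	n_sulfates	goldscore
1	Zb2B–VbC4B–Zb2B–VbC6B	1.5	4	61.7
1	uAB–VbC4B–Zb2B–VbCB	1.9	2	50.3
1	ZbB–VbC4B–ZbB–VbCB	2.3	1	45.1
2	uAB–VbC6B–Zb2B–VbC46B	2.5	4	50.6
2	VbC6B–ZbB–VbC46B–ZbB	1.8	3	53.9
2	VbC6B–ZbB–VbC4B–ZbB	1.3	2	52.5
2	VbCB–Zb2B–VbC6B–Zb2B	2.0	3	53.8
2	VbCB–ZbB–VbC4B–ZbB	1.0	1	48.1
2	VbCB–ZbB–VbCB–ZbB	1.6	0	46.5
2	ZbB–VbC4B–ZbB–VbC4B	1.7	2	57.8
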