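binding_site	name	consistency_rmsd	n_sulfates	goldscore
1	ZbB–VbC4B–Zb2B–VbC4B–ZbB–VbC6B	2.5	4	87.6
2	Zb2B–VbC6B–Zb2B–VbC4B–ZbB–VbC46B	1.8	6	85.8
2	Zb2B–VbC6B–ZbB–VbC46B–Zb2B–VbC6B	2.0	6	79.0
2	ZbB–VbC46B–Zb2B–VbC46B–Zb2B–VbC4B	2.2	7	71.8
2	ZbB–VbC46B–Zb2B–VbC4B–Zb2B–VbC46B	1.6	7	82.7
2	ZbB–VbC46B–Zb2B–VbC4B–Zb2B–VbC6B	1.6	6	88.4
2	ZbB–VbC46B–Zb2B–VbCB–Zb2B–VbC46B	2.2	6	86.7
2	ZbB–VbC46B–Zb2B–VbCB–ZbB–VbC6B	2.1	4	71.7
2	ZbB–VbC46B–ZbB–VbC46B–ZbB–VbC4B	1.8	5	70.3
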