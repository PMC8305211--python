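linkage	phi	psi	phi_atoms	psi_atoms
GlcA(1->3)GalNAc	-81	-129	O5-C1-O3'-C3'	C1-O3'-C3'-C2'
GalNAc(1->4)GlcA	-69	131	O5-C1-O4'-C4'	C1-O4'-C4'-C3'
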