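stack	dh_cal_mol	ds_cal_mol_k	provenance
AA/UU	-6820	-19.0	Xia et al. 1998 Biochemistry 37:14719, 1 M NaCl RNA/RNA Watson-Crick
AU/AU	-9380	-26.7	Xia et al. 1998 Biochemistry 37:14719, 1 M NaCl RNA/RNA Watson-Crick
UA/UA	-7690	-20.5	Xia et al. 1998 Biochemistry 37:14719, 1 M NaCl RNA/RNA Watson-Crick
CU/AG	-10480	-27.1	Xia et al. 1998 Biochemistry 37:14719, 1 M NaCl RNA/RNA Watson-Crick
CA/UG	-10440	-26.9	Xia et al. 1998 Biochemistry 37:14719, 1 M NaCl RNA/RNA Watson-Crick
GU/AC	-11400	-29.5	Xia et al. 1998 Biochemistry 37:14719, 1 M NaCl RNA/RNA Watson-Crick
GA/UC	-12440	-32.5	Xia et al. 1998 Biochemistry 37:14719, 1 M NaCl RNA/RNA Watson-Crick
CG/CG	-10640	-26.7	Xia et al. 1998 Biochemistry 37:14719, 1 M NaCl RNA/RNA Watson-Crick
GG/CC	-13390	-32.7	Xia et al. 1998 Biochemistry 37:14719, 1 M NaCl RNA/RNA Watson-Crick
GC/GC	-14880	-36.9	Xia et al. 1998 Biochemistry 37:14719, 1 M NaCl RNA/RNA Watson-Crick
INITIATION	3610	-1.5	Xia et al. 1998 Biochemistry 37:14719, duplex initiation
TERMINAL_AU	3720	10.5	Xia et al. 1998 Biochemistry 37:14719, per terminal A-U pair penalty
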