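Angiogenesis	angiogenesis	ANGPT2	APLN	CD34	CD93	CDH5	CLEC14A	CXorf36	ECSCR	EGFL7	ELTD1	EMCN	ENG	ESAM	ESM1	GPR116	ICAM2	JAM2	KDR	LDB2	MMRN1	MMRN2	MYCT1	NOTCH4	PCDH12	PECAM1	PLVAP	PTPRB	RAMP2	RAMP3	RHOJ	ROBO4	S1PR1	SHE	SOX18	SPARCL1	TEK	TIE1	TM4SF18	TSPAN7	VWF
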