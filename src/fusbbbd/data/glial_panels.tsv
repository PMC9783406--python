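panel	cell_type	subtype	gene
pan_microglia	microglia	pan	CD68
pan_microglia	microglia	pan	Aif1
pan_microglia	microglia	pan	Ccl12
M1	microglia	M1	Serpine1
M1	microglia	M1	CD40
M1	microglia	M1	Gbp4
M2	microglia	M2	Arg1
M2	microglia	M2	Gpr84
M2	microglia	M2	Apod
pan_astrocyte	astrocyte	pan	Serpina3n
pan_astrocyte	astrocyte	pan	Vim
pan_astrocyte	astrocyte	pan	Gfap
pan_astrocyte	astrocyte	pan	Lcn2
A1	astrocyte	A1	H2-D1
A1	astrocyte	A1	Gbp2
A1	astrocyte	A1	Psmb8
A1	astrocyte	A1	Srgn
A2	astrocyte	A2	Emp1
A2	astrocyte	A2	Tgm1
A2	astrocyte	A2	Tm4sf1
A2	astrocyte	A2	CD14
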