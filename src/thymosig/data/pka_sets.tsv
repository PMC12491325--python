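# Side-chain pKa values for ionizable residues, by reference set.
# sign: +1 = protonated form is positive (H, K, R); -1 = deprotonated form
# is negative (D, E, C, Y). Terminal pKa values are listed under residue
# codes Nterm/Cterm and used only when termini are included.
set	aa	pka	sign
lehninger	D	3.65	-1
lehninger	E	4.25	-1
lehninger	C	8.18	-1
lehninger	Y	10.07	-1
lehninger	H	6.00	1
lehninger	K	10.53	1
lehninger	R	12.48	1
lehninger	Nterm	9.69	1
lehninger	Cterm	2.34	-1
emboss	D	3.9	-1
emboss	E	4.1	-1
emboss	C	8.5	-1
emboss	Y	10.1	-1
emboss	H	6.5	1
emboss	K	10.8	1
emboss	R	12.5	1
emboss	Nterm	8.6	1
emboss	Cterm	3.6	-1
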