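# Per-residue hydrophobicity scales. kyte_doolittle: Kyte & Doolittle (1982)
# hydropathy index (positive = hydrophobic). hopp_woods: Hopp & Woods (1981)
# hydrophilicity (sign-flipped convention; kept as published).
aa	kyte_doolittle	hopp_woods
A	1.8	-0.5
R	-4.5	3.0
N	-3.5	0.2
D	-3.5	3.0
C	2.5	-1.0
Q	-3.5	0.2
E	-3.5	3.0
G	-0.4	0.0
H	-3.2	-0.5
I	4.5	-1.8
L	3.8	-1.8
K	-3.9	3.0
M	1.9	-1.3
F	2.8	-2.5
P	-1.6	0.0
S	-0.8	0.3
T	-0.7	-0.4
W	-0.9	-3.4
Y	-1.3	-2.3
V	4.2	-1.5
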