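# Physicochemical property classes of the 20 standard amino acids
# (Livingstone & Barton rendering of the Taylor Venn diagram; 1 = residue
# belongs to the class). Used by the set-valued conservation score Cs.
aa	hydrophobic	polar	small	tiny	aliphatic	aromatic	positive	negative	charged	proline
A	1	0	1	1	0	0	0	0	0	0
C	1	1	1	1	0	0	0	0	0	0
D	0	1	1	0	0	0	0	1	1	0
E	0	1	0	0	0	0	0	1	1	0
F	1	0	0	0	0	1	0	0	0	0
G	1	0	1	1	0	0	0	0	0	0
H	1	1	0	0	0	1	1	0	1	0
I	1	0	0	0	1	0	0	0	0	0
K	1	1	0	0	0	0	1	0	1	0
L	1	0	0	0	1	0	0	0	0	0
M	1	0	0	0	0	0	0	0	0	0
N	0	1	1	0	0	0	0	0	0	0
P	0	0	1	0	0	0	0	0	0	1
Q	0	1	0	0	0	0	0	0	0	0
R	0	1	0	0	0	0	1	0	1	0
S	0	1	1	1	0	0	0	0	0	0
T	1	1	1	0	0	0	0	0	0	0
V	1	0	1	0	1	0	0	0	0	0
W	1	1	0	0	0	1	0	0	0	0
Y	1	1	0	0	0	1	0	0	0	0
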