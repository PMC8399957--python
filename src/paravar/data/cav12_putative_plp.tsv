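# Published reference set: 36 hCav1.2 (CACNA1C) variants of uncertain
# significance reclassified as putative pathogenic/likely-pathogenic by the
# consensus of a meta-predictor call and paralogue annotation support.
# "paralogues" lists the supporting paralogue P/LP variants as
# GENE-Change tokens, comma-joined.
variant	location	paralogues
A180T	DI-S2/S3	SCN5A-A178G,SCN1A-A175V,SCN1A-A175T
T330M	DI-S5/S6	SCN1A-Y349C
G342S	DI-S5/S6	SCN5A-G351V,SCN5A-G351D
T344I	DI-S5/S6	SCN1A-T363R,SCN1A-T363P,SCN5A-T353I
T366M	DI-S5/S6	SCN1A-E385Q
G377A	DI-S5/S6	SCN5A-G386R,SCN5A-G386E
G402R	DI-DII	CACNA1E-G348R,SCN1A-A420V,CACNA1D-G403D,CACNA1F-G369D
W528G	DII-S1	SCN1A-L772P
A562T	DII-S2	CACNA1H-V831M
A565T	DII-S2	SCN5A-G758E
I630V	DII-S4	SCN1A-L869S,SCN1A-L869F
L644W	DII-S4/S5	SCN9A-I859T,SCN3A-I875T,SCN4A-I693T,SCN8A-I868T
I651N	DII-S4/S5	SCN5A-L839P,CACNA1E-I603L,SCN8A-L875Q,CACNA1A-I614M,SCN1A-L890P
I651V	DII-S4/S5	SCN5A-L839P,CACNA1E-I603L,SCN8A-L875Q,CACNA1A-I614M,SCN1A-L890P
L658P	DII-S5	NALCN-T513N,SCN1A-L897S,SCN1A-L897F
F692I	DII-S5/S6	SCN2A-F928C
G705R	DII-S5/S6	SCN1A-G950E,SCN1A-G950R
I751V	DII-DIII	CACNA1D-I750F,CACNA1A-I712V,CACNA1E-I701V,CACNA1F-I756T,CACNA1D-I750M
A757P	DII-DIII	SCN2A-S987I
E760K	DII-DIII	SCN1A-D998G
L912I	DIII-S1	SCN1A-L1230F
I932T	DIII-S2	SCN1A-M1251R,SCN5A-L1238P
F936C	DIII-S2	SCN1A-A1255D,SCN1A-A1255P
K1074R	DIII-S5/S6	SCN5A-K1359N
D1119N	DIII-S5/S6	SCN1A-D1416G
A1124V	DIII-S5/S6	SCN1A-G1421R,SCN1A-G1421E,SCN5A-G1408R
V1131I	DIII-S5/S6	CACNA1A-V1456L,SCN1A-V1428A,SCN1A-V1428F
E1135G	DIII-S5/S6	SCN1A-K1432I,SCN5A-K1419E,SCN2A-K1422E
E1135K	DIII-S5/S6	SCN1A-K1432I,SCN5A-K1419E,SCN2A-K1422E
G1136A	DIII-S5/S6	SCN1A-G1433V,SCN5A-G1420R,SCN5A-G1420V,SCN1A-G1433R,SCN1A-G1433E
G1153D	DIII-S5/S6	SCN1A-Q1450K,SCN1A-Q1450R
A1174S	DIII-S6	SCN5A-S1458Y,SCN1A-S1471F
F1246L	DIV-S1	SCN4A-M1360V,SCN2A-M1538I
I1373V	DIV-S4	SCN1A-P1632S
I1421V	DIV-S5	SCN1A-I1683F,SCN4A-I1495F,SCN1A-I1683T
A1617T	C-term	SCN5A-V1861I
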