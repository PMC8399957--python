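# Published per-gene missense variant counts for the human Cav1.2 channel
# and its 20 paralogues (voltage-gated Na+/Ca2+ channels plus the NALCN
# leak channel): curated benign, pathogenic/likely-pathogenic (P/LP) and
# uncertain-significance (VUS) categories.
gene	channel	benign	plp	vus
CACNA1A	hCav2.1	5	60	346
CACNA1B	hCav2.2	48	0	10
CACNA1C	hCav1.2	21	22	309
CACNA1D	hCav1.3	4	7	46
CACNA1E	hCav2.3	36	17	18
CACNA1F	hCav1.4	39	28	39
CACNA1G	hCav3.1	42	5	45
CACNA1H	hCav3.2	116	21	454
CACNA1I	hCav3.3	61	0	1
CACNA1S	hCav1.1	57	11	290
NALCN	hNavi2.1	18	31	17
SCN1A	hNav1.1	18	605	482
SCN2A	hNav1.2	15	166	301
SCN3A	hNav1.3	16	8	202
SCN4A	hNav1.4	47	78	312
SCN5A	hNav1.5	43	350	705
SCN7A	hNav2.1	65	0	0
SCN8A	hNav1.6	6	93	249
SCN9A	hNav1.7	11	32	505
SCN10A	hNav1.8	66	3	291
SCN11A	hNav1.9	29	12	230
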