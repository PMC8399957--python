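# Reconstructed transmembrane topology of the human Cav1.2 alpha-1 subunit
# (CACNA1C, UniProt Q13936-style segment boundaries, 2221 residues).
# Borders are a reconstruction consistent with published variant->region
# assignments for this channel; they are not an authoritative UniProt export.
# Coordinates are 1-based inclusive protein residue indices.
name	start	end	class
N-term	1	124	terminus
DI-S1	125	145	tm_segment
DI-S1/S2	146	153	linker
DI-S2	154	174	tm_segment
DI-S2/S3	175	187	linker
DI-S3	188	208	tm_segment
DI-S3/S4	209	218	linker
DI-S4	219	239	tm_segment
DI-S4/S5	240	254	linker
DI-S5	255	277	tm_segment
DI-S5/S6	278	383	p_loop
DI-S6	384	400	tm_segment
DI-DII	401	524	linker
DII-S1	525	545	tm_segment
DII-S1/S2	546	555	linker
DII-S2	556	576	tm_segment
DII-S2/S3	577	589	linker
DII-S3	590	610	tm_segment
DII-S3/S4	611	620	linker
DII-S4	621	641	tm_segment
DII-S4/S5	642	655	linker
DII-S5	656	678	tm_segment
DII-S5/S6	679	708	p_loop
DII-S6	709	733	tm_segment
DII-DIII	734	890	linker
DIII-S1	891	915	tm_segment
DIII-S1/S2	916	925	linker
DIII-S2	926	946	tm_segment
DIII-S2/S3	947	960	linker
DIII-S3	961	981	tm_segment
DIII-S3/S4	982	993	linker
DIII-S4	994	1014	tm_segment
DIII-S4/S5	1015	1030	linker
DIII-S5	1031	1053	tm_segment
DIII-S5/S6	1054	1165	p_loop
DIII-S6	1166	1190	tm_segment
DIII-DIV	1191	1240	linker
DIV-S1	1241	1261	tm_segment
DIV-S1/S2	1262	1270	linker
DIV-S2	1271	1291	tm_segment
DIV-S2/S3	1292	1305	linker
DIV-S3	1306	1326	tm_segment
DIV-S3/S4	1327	1354	linker
DIV-S4	1355	1380	tm_segment
DIV-S4/S5	1381	1400	linker
DIV-S5	1401	1425	tm_segment
DIV-S5/S6	1426	1500	p_loop
DIV-S6	1501	1525	tm_segment
C-term	1526	2221	terminus
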