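group	cluster	chip_hits	input_hits	printed_ratio	repeat_type
high_abundance	CL3	42004	38140	1.10	TCAST satellite DNA
high_abundance	CL4	31220	27988	1.12	TCAST satellite DNA
high_abundance	CL10	23779	14796	1.61	28S rDNA-like
high_abundance	CL12	28617	19621	1.46	LINE-1 element ORF2 protein (LOC658088)
high_abundance	CL13	42765	26017	1.64	18S rDNA-like
high_abundance	CL19	12573	9903	1.27	Cast6 satellite DNA
high_abundance	CL20	10166	7557	1.35	DNA transposon (Helitron)-like
high_abundance	CL48	10565	5052	2.09	tandem repeat
enriched	CL141	488	158	3.09	non-LTR retrotransposon SARTTc1
enriched	CL143	460	192	2.40	non-LTR retrotransposon SARTTc1
enriched	CL169	495	238	2.08	non-LTR retrotransposon SARTTc3
enriched	CL198	210	99	2.12	DNA transposon (Polinton)-like
enriched	CL234	402	158	2.54	LTR retrotransposon (Copia)-like
enriched	CL253	288	110	2.62	non-LTR retrotransposon SARTTc3
enriched	CL264	337	145	2.32	non-LTR retrotransposon SARTTc1
enriched	CL270	732	342	2.14	5S rDNA
enriched	CL298	296	137	2.16	non-LTR retrotransposon (Jockey)-like
enriched	CL336	177	70	2.53	non-LTR retrotransposon SARTTc3
enriched	CL391	1591	602	2.64	unknown
enriched	CL394	442	85	5.20	uncharacterized LOC107399056 partial mRNA
enriched	CL399	202	61	3.31	non-LTR retrotransposon SARTTc1
enriched	CL469	145	53	2.74	non-LTR retrotransposon SARTTc1
enriched	CL611	216	78	2.77	tigger element-derived protein 4 (LOC103314401)
enriched	CL669	118	58	2.03	unknown
enriched	CL711	174	78	2.23	non-LTR retrotransposon SARTTc3
enriched	CL797	115	41	2.80	mobile element jockey-like (LOC103314666)
enriched	CL942	133	39	3.41	unknown
enriched	CL992	118	34	3.47	non-LTR R2 retrotransposon
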