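chrom	pos	rsid	ref	alt	ancestral	gene	consequence	daf_shp_seq	daf_tbn_seq	daf_han_seq	daf_tbn_target	daf_shp_target	daf_shp_seq2	daf_eas	daf_sas	daf_afr	daf_eur	daf_amr	cadd	gerp
8	107691513	rs28921397	A	G	A	OXR1	missense	0.5	0.0000	0.0000	0.0172	0.0789	0.0000	0.0029	0.0000	0.0000	0.0000	0.0000	31	5.96
8	108264111	.	A	G	A	ANGPT1	missense	0.5	0.0152	0.0000	0.0086	0.0724	0.0000						31	5.9
17	19645417	.	T	A	T	ALDH3A1	missense	0.4	0.0000	0.0000	0.0000	0.0987	0.0000						31	4.49
3	196921405	rs527829647	A	G	A	DLG1	missense	0.3	0.0000	0.0000	0.0129	0.0789	0.0000	0.0011	0.0000	0.0000	0.0000	0.0000	22.3	5.17
12	117768315	rs549340789	G	A	G	NOS1	missense	0.3	0.0000	0.0000	0.0086	0.0855	0.0000	0.0022	0.0000	0.0000	0.0000	0.0000	17.79	4.74
10	45956828	rs3764990	G	A	G	MARCH8	missense	0.4	0.0303	0.0256	0.0905	0.1974	0.2500	0.0528	0.0226	0.0143	0.0787	0.0293	18.84	5.65
7	21948010	rs200891942	A	G	A	CDCA7L	missense	0.3	0.0152	0.0000	0.0129	0.1053	0.0000	0.0010	0.0000	0.0000	0.0000	0.0000	21.1	5.95
2	37232879	rs2302657	A	C	A	HEATR5B	missense	0.3	0.0152	0.0128	0.0086	0.1067	0.2500	0.0325	0.0023	0.0000	0.0000	0.0000	16.87	5.63
2	109545691	rs61761321	T	C	T	EDAR	missense	0.3	0.0152	0.1795	0.0345	0.1447	0.0000	0.0910	0.0023	0.0012	0.0000	0.0000	10.27	4.09
1	91405998	rs149597385	C	T	C	ZNF644	missense	0.3	0.0152	0.0000	0.0259	0.1184	0.0000	0.0100	0.0012	0.0000	0.0000	0.0000	32	4.63
1	156551628	rs116035113	G	T	G	TTC24	missense	0.3	0.0152	0.0000	0.0474	0.1250	0.0000	0.0030	0.0010	0.0475	0.0125	0.0124	23.9	4.83
2	46707674	rs116983452	C	T	C	TMEM247	missense	0.4	0.2121	0.0256	0.7241	0.6389	1.0000	0.0207	0.0035	0.0000	0.0000	0.0000	11.18	2.97
1	231557623	rs186996510	G	C	G	EGLN1	missense	0.1	0.5910	0.0385	0.5500	0.4800	0.2500	0.0100	0.0020	0.0000	0.0000	0.0020	14.73	3.51
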