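gene_name	accession	route	n_offpathway	length	disorder_content	n_ldr_30	n_dbr	dbr_residue_ratio	functional_group
DAB1	O75553	CLTR	25	588	51.36	3	10	35.54	ASP
ARRB2	P32121	CLTR	25	409	15.65	0	1	2.44	ASP
DNM1	Q05193	CLTR	23	864	22.34	1	8	16.09	EARP
SEC13	P55735	COPII	22	322	6.52	0	0	0.00	COAT
ARRB1	P49407	CLTR	18	418	21.53	1	4	11.72	ASP
DNM2	P50570	CLTR	18	870	23.33	1	9	12.18	EARP
SH3KBP1	Q96B97	CLTR	15	665	66.77	2	15	46.32	ASP
EPS15	P42566	CLTR	13	896	49.00	4	14	23.10	ASP
NUMB	P49757	CLTR	12	651	61.29	5	13	37.48	ASP
CLTA	P09496	CLTR	10	248	60.08	3	3	44.76	COAT
DAB2	P98082	CLTR	10	770	74.16	6	24	49.74	ASP
CLTC	Q00610	CLTR	10	1675	1.07	0	0	0.00	COAT
SH3GL2	Q99962	CLTR	10	352	33.24	1	8	19.60	UCP
SYNJ1	O43426	CLTR	9	1573	33.76	3	12	24.92	EARP
ITSN1	Q15811	CLTR	9	1721	28.41	5	14	9.59	ASP
HGS	O14964	CLTR	8	777	55.86	4	12	31.15	ASP
AP2A1	O95782	CLTR	7	977	14.74	2	4	8.60	ASP
COPB2	P35606	COPI	6	906	9.16	1	3	5.08	COAT
AP2B1	P63010	CLTR	6	937	4.16	0	1	1.28	ASP
AP2M1	Q96CW1	CLTR	5	435	4.83	0	1	1.38	ASP
DNM3	Q9UQ16	CLTR	5	869	22.32	1	6	13.81	EARP
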