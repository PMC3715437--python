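gene	transcript_id	switch_score	routes	functional_group	protein_span	pct_disordered_in_tse	more_disordered_than_reference	dbrs_overlapping	dbrs_flanking
AP1B1	ENST00000405198	1	CLTR	ASP	667-674	75	yes		649-666
BIN1	ENST00000259238	1	CLTR	ASP	255-269	100	yes	246-270
PICALM	ENST00000341783	0.92	CLTR	ASP	420-469	18	no
CLTB	ENST00000310418	0.9	CLTR	COAT	156-174	15.79	no	155-177
AP1S2	ENST00000340245	0.8	CLTR	ASP	140-153	0	no
CLTA	ENST00000242285	0.77	CLTR	COAT	180-192	0	no	168-187
ARRB1	ENST00000420843	0.75	CLTR	ASP	333-341	0	no		342-352
TMED2	ENST00000438031	0.74	COPI;COPII	UCP	125-132	100	yes
BIN1	ENST00000351659	0.74	CLTR	ASP	174-204	0	no
EPN1	ENST00000270460	0.73	CLTR	ASP	202-226	100	yes	204-223
BIN1	ENST00000393041	0.69	CLTR	ASP	305-340	100	yes	306-385
ARRB2	ENST00000381488	0.64	CLTR	ASP	8-18	0	no
GGA1	ENST00000343632	0.62	CLTR	ASP	278-313	44.44	yes	279-299	314-337
ARRB2	ENST00000269260	0.59	CLTR	ASP	8-18	0	no
SH3KBP1	ENST00000379716	0.57	CLTR	ASP	261-303	100	yes	256-271;280-357
BIN1	ENST00000409400	0.57	CLTR	ASP	304-333	100	yes	273-350
SAR1A	ENST00000373239	0.54	COPII	EARP	20-59	0	no
GGA1	ENST00000343632	0.5	CLTR	ASP	278-313	44.44	yes	279-299
EPS15L1	ENST00000248070	0.5	CLTR	ASP	794-862	94.20	yes	797-845;853-864
SAR1A	ENST00000373239	0.49	COPII	EARP	1-59	0	no
AX747833	ENST00000359560	0.46	CLTR	ASP	355-402	83.33	yes	358-380;391-422
EPN1	ENST00000411543	0.46	CLTR	ASP	1-16	0	no
ARFGAP3	ENST00000263245	0.42	COPI	EARP	355-399	33.33	yes	350-358
EPN3	ENST00000268933	0.37	CLTR	ASP	228-254	92.59	yes	236-250
DAB2	ENST00000320816	0.36	CLTR	ASP	230-446	99.08	yes	232-243;253-267;270-290;309-316;330-355;358-378;384-434;446-464
DNM1	ENST00000341179	0.36	CLTR	EARP	875-881	100	yes	867-881
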