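gene	half	count_E	pct_E	count_M	pct_M	fold_printed	direction
FADS2	spheroid	147	48	55	31	1.6	E-over-M
CTSV	spheroid	41	13	9	5	2.7	E-over-M
S100B	spheroid	61	20	3	2	12.0	E-over-M
SCG2	spheroid	2	1	0	0	1.0	E-over-M
BAMBI	spheroid	58	19	28	16	1.2	E-over-M
DUSP6	spheroid	64	21	23	13	1.6	E-over-M
LCP1	spheroid	13	4	3	2	2.6	E-over-M
RBBP7	spheroid	168	55	63	35	1.6	E-over-M
QPCT	spheroid	27	9	22	12	0.7	E-over-M
SOX2	spheroid	52	17	10	6	3.1	E-over-M
THY1	spheroid	44	14	3	2	8.7	E-over-M
ZEB1	spheroid	4	1	2	1	1.2	E-over-M
BMI1	spheroid	17	6	6	3	1.7	E-over-M
CD24	spheroid	141	46	78	43	1.1	E-over-M
NANOG	spheroid	8	3	11	6	0.4	E-over-M
MYC	spheroid	118	39	39	22	1.8	E-over-M
PROM1	spheroid	5	2	14	8	0.2	E-over-M
RAB33A	spheroid	22	7	3	2	4.3	E-over-M
GNG2	spheroid	19	6	1	1	11.2	E-over-M
ACSL3	spheroid	31	10	14	8	1.3	E-over-M
HMGCS1	spheroid	38	12	17	9	1.3	E-over-M
FXYD6	spheroid	32	10	4	2	4.7	E-over-M
MLF1	spheroid	19	6	2	1	5.6	E-over-M
ZRSR2	spheroid	35	11	10	6	2.1	E-over-M
PTH1R	spheroid	1	0	0	0	0.0	E-over-M
S100A1	spheroid	8	3	5	3	0.9	E-over-M
MVK	spheroid	20	7	5	3	2.4	E-over-M
TMIE	spheroid	0	0	0	0	0.0	E-over-M
SERPINF1	spheroid	45	15	16	9	1.7	E-over-M
THOC6	spheroid	85	28	29	16	1.7	E-over-M
GNS	spheroid	42	14	24	13	1.0	E-over-M
CHAC1	spheroid	72	24	24	13	1.8	E-over-M
CLGN	spheroid	46	15	5	3	5.4	E-over-M
KIF1A	spheroid	42	14	3	2	8.3	E-over-M
BTG1	spheroid	205	67	95	53	1.3	E-over-M
SOD3	spheroid	14	5	7	4	1.2	E-over-M
RMND5B	spheroid	29	10	15	8	1.1	E-over-M
ZCCHC3	spheroid	53	17	10	6	3.1	E-over-M
SFN	serum	5	2	18	10	6.1	M-over-E
ANKRD1	serum	15	5	37	21	4.2	M-over-E
KRTAP2-3	serum	1	0	1	1	1.7	M-over-E
CA2	serum	0	0	0	0	0.0	M-over-E
CPA4	serum	4	1	1	1	0.4	M-over-E
EPHB3	serum	1	0	2	1	3.4	M-over-E
PLEK2	serum	8	3	2	1	0.4	M-over-E
IGFBP3	serum	2	1	1	1	0.8	M-over-E
DMKN	serum	62	20	43	24	1.2	M-over-E
CAPG	serum	51	17	34	19	1.1	M-over-E
TAGLN	serum	11	4	2	1	0.3	M-over-E
FXYD5	serum	21	7	6	3	0.5	M-over-E
KRT19	serum	76	25	79	44	1.8	M-over-E
ID4	serum	73	24	51	28	1.2	M-over-E
ARL4C	serum	23	8	23	13	1.7	M-over-E
PFKP	serum	19	6	15	8	1.3	M-over-E
MT1L	serum	18	6	6	3	0.6	M-over-E
ALDH1A1	serum	24	8	14	8	1.0	M-over-E
VPS13D	serum	4	1	4	2	1.7	M-over-E
ID1	serum	2	1	0	0	0.0	M-over-E
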