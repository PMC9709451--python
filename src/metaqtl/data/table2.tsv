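name	chr	position_cm	flank_left	flank_right	n_qtls	n_traits	traits	avg_pve_pct
MQTL1.1	1	46.48	RM6324	C11461	8	3	SF,GNP,TGW	11.09
MQTL1.2	1	62.9	GNMS3879	RM583	1	1	GNP	27.6
MQTL1.3	1	84.25	RM600	RM572	2	2	SF,TGW	4.94
MQTL1.4	1	116.8	RM23	RM24	1	1	SF	4.8
MQTL1.5	1	176.13	TP1E3B	RM3143	4	2	GNP,TGW	9.03
MQTL1.6	1	199.86	C10980S	C1162	3	3	SF,TGW	16.05
MQTL1.7	1	224	C1162	RM212	4	2	SF,TGW	5.81
MQTL1.8	1	257.89	G54	RM5310	1	1	SF	0.09
MQTL2.1	2	2.19	C60318SC	RRH02_2	1	1	GNP	18.22
MQTL2.2	2	27.14	RM6911	RM324	5	2	PN,TGW	7.85
MQTL2.3	2	65.83	S20660A	RG157	3	1	TGW	8.53
MQTL2.4	2	118.36	C920	L107	3	1	SF	4.73
MQTL2.5	2	145.51	Rf2	RM240	4	3	SF,GNP,TGW	11.35
MQTL2.6	2	161.74	Y8007R	RM208	7	3	SF,GNP,TGW	7.87
MQTL3.1	3	57.62	RM5474	GNMS3875	4	3	SF,GNP,TGW	0.86
MQTL3.2	3	115.3	RM254	GNMS1140	4	2	SF,TGW	12.8
MQTL3.3	3	153.71	GS3	RM15283	3	2	SF,TGW	11.38
MQTL3.4	3	191.94	RM6681	RM426	4	1	TGW	17.11
MQTL3.5	3	197.49	RM426	S10742	14	4	SF,GNP,PN,TGW	10.52
MQTL3.6	3	205.15	S10742	RM468	2	1	TGW	23.7
MQTL3.7	3	224.72	RM200	S10057A	4	2	SF,TGW	8.41
MQTL3.8	3	253.74	W1871A	R689	5	2	SF,TGW	6.9
MQTL3.9	3	258.92	R689	S13122	5	3	SF,GNP,TGW	12.13
MQTL4.1	4	30.25	RM6314	RM2536	2	1	SF	11.4
MQTL4.2	4	130.54	RM273	RG776A	7	3	SF,GNP,TGW	8.89
MQTL4.3	4	143.05	RG776A	Prp2	2	1	GNP	11.13
MQTL4.4	4	160.52	PSM115	RM5709	1	1	SF	0.19
MQTL4.5	4	172.31	RM7509	C1016	5	2	GNP,TGW	4.98
MQTL5.1	5	16.88	Rpr2	RM153	2	1	SF	7.79
MQTL5.2	5	64.27	E61293S	Pi23	13	3	SF,GNP,TGW	11.77
MQTL5.3	5	67.95	Pi23	RM509	4	3	SF,GNP,TGW	10.00
MQTL5.4	5	81.44	RM161	RM305	1	1	TGW	18.13
MQTL5.5	5	104.18	RM3351	RZ225	6	3	SF,GNP,TGW	9.14
MQTL6.1	6	69.42	RM7088	TaA	4	2	SF,GNP	10.35
MQTL6.2	6	89.51	RM190	VB3	2	2	SF,TGW	2.8
MQTL6.3	6	116.23	LDH	G8023	6	3	SF,GNP,TGW	8.16
MQTL6.4	6	152.51	RM238B	C1	1	1	SF	0.25
MQTL6.5	6	162.41	RG468	Y1124L	3	3	SF,GNP,TGW	7.97
MQTL6.6	6	229.01	GNMS3878	RM3827	2	1	GNP	6.9
MQTL6.7	6	270.28	RM4447	E31330S	4	2	SF,TGW	6.14
MQTL7.1	7	88.77	RM21345	RM215	2	1	TGW	10.46
MQTL7.2	7	109.5	RM214	R1788	3	2	SF,GNP	9.34
MQTL7.3	7	164.15	RM455	RM1135	1	1	SF	0.19
MQTL7.4	7	179.68	RM1135	R2286	5	3	SF,GNP,TGW	8.61
MQTL7.5	7	201.31	FOR1	R10022S	4	2	SF,GNP,TGW	4.43
MQTL7.6	7	225.17	S162745	RM1335	4	2	GNP,TGW	9.42
MQTL8.1	8	97.84	S779	C12515	1	1	SF	15.3
MQTL8.2	8	107.56	cen8	RM556	10	3	SF,GNP,TGW	6.64
MQTL9.1	9	56.41	EM14_6	RM107	1	1	SF	4.0
MQTL9.2	9	89.89	RM566	ME4_10	4	4	SF,GNP,PN,TGW	6.51
MQTL9.3	9	108.16	B163	RM3769	5	3	SF,GNP,PN	3.59
MQTL9.4	9	139.64	G293	RM201	1	1	TGW	8.07
MQTL10.1	10	100.03	RM101	RM2696	2	2	GNP,TGW	16.28
MQTL10.2	10	173.08	RZ337	R1877	6	2	SF,TGW	7.58
MQTL10.3	10	190.05	RG134	RMg65	4	2	SF,TGW	16.2
MQTL11.1	11	13.15	SINE1r6	S10637B	2	2	SF,GNP	14.95
MQTL11.2	11	40.39	TP1s1	RG1094	3	2	SF,TGW	7.52
MQTL11.3	11	65.37	S2137	E435sA	3	2	GNP,PN	4.4
MQTL11.4	11	131.53	G389	GNMS3600	2	2	GNP,PN	5.75
MQTL12.1	12	49.27	P4-E26M47.222	P1	1	1	TGW	24.81
MQTL12.2	12	58.07	RG457	Sdh1	8	2	SF,GNP	7.81
MQTL12.3	12	99.68	RG323	GNMS3766	3	2	SF,GNP,TGW	4.02
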