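study_id	parents	pop_type	pop_size	n_markers	marker_types	traits	citation
S01	Zhenshan 97B x Milyang 46	RIL	209	158	RFLP,SSLP	SF,PN,TGW	B129
S02	IR64 x Azucena	DH	135	253	RFLP,RAPD,SSR	SF,TGW	B30
S03	IR64 x IRGC 105491	BC	400	165	SSR,RFLP	SF,PN,GNP	B88
S04	IRGC 105491 x Jefersson	BC	353	153	SSR,RFLP	SF,PN,GNP	B98
S05	58025A x IC22015	BC	251	80	SSR	SF,PN,GNP	B67
S06	Milyang 23 x Akihikari	RIL	155	273	SSR,RFLP	GNP	B96
S07	Minghui 63 x B5	RIL	187	244	SSR,RFLP	PN,GNP	B117
S08	T226 x T219	RIL	202	181	SSR	SF	B73
S09	Suweon365 x Chucheongbyeo	RIL	231	221	SSR,AFLP,MITE	PN,GNP	B49
S10	Junambyeo x IR71033	F2	146	338	STS	SF,PN	B76
S11	Ipumbyeo x Dasanbyeo	BC	252	196	STS	SF	B72
S12	Tarommahalli x Khazar	F2	192	74	SSR	GNP	B78
S13	Koshihikari x Kasalath	BC	182	162	RFLP	TGW	B53
S14	Minghui 63 x Teqing	RIL	190	133	SSR	TGW	B57
S15	Gharib x Sepidroud	F2	236	155	SSR	PN,TGW	B79
S16	YJCW x 93-11	BC	354	187	SSR	SF,PN,GNP,TGW	B26
S17	Zhong 156 x Gumei 2	RIL	276	198	SSR	PN,GNP,SF,TGW	B11
S18	Pusa 1266 x Pusa Basmati 1	RIL	161	175	SSR	GNP,PN	B21
S19	Dasanbyeo x TR 22183	BC	166	218	SSR,STS	SF	B16
S20	Nanyangzhan x Chuan7	RIL	185	164	SSR	TGW	B6
S21	Pusa1266 x Jaya	RIL	310	162	SSR	SF,PN,GNP	B66
S22	XieqingzaoB x Zhonghui9308	RIL	266	177	SSR	SF,PN,TGW	B51
S23	cv. D50 x cv. HB277	RIL	116	102	SSR	TGW	B97
S24	Guanghui 116 x LaGrue	RIL	307	119	SSR	GNP,TGW,SF	B128
S25	Swarna x IRGC81848	BC	472	175	SSR	TGW	B92
S26	HWC-line x Dasan x Hwacheong	F2	190	157	SSR,STS,FNP	SF,TGW	B87
S27	Nipponbare x 93-11	RIL	266	131	SSR	GNP,TGW	B101
S28	HP x Nipponbare	F2	93	90	SSR,InDel	GNP	B99
S29	M201 x JY293	RIL	234	32	SSR,SLAF	TGW	B111
S30	Xieqingzao B x Zhonghui 9308	RIL	138	198	SSR	SF,PN,TGW	B118
S31	N040212 x Nipponbare	BC	146	34	SSR	SF	B2
S32	NYZ x Ce253	F2	188	110	SSR,InDel	TGW	B108
S33	G46B x K1075	RIL	182	492	SSR	TGW	B27
S34	HR1128 x Nipponbare	BC	331	37	SSR,InDel	GNP	B91
S35	R998 x Francis	RIL	213	3016	SNP	PN,GNP,TGW	B130
S36	Dasanbyeo x TR22183	RIL	179	162	SSR,STS	SF,PN,TGW	B46
S37	9IL188 x 9311	F2	152	326	SSR	GNP	B32
S38	Nagdong x Cheongcheong	RIL	90	154	SSR	PN,GNP	B39
S39	Teqing x IRBB	RIL	250	68	SSR,InDel	TGW	B123
S40	Xuishui09 x IR2061	BC	459	6181	SNP	TGW	B105
S41	K1561 x G1025	RIL	201	5826	SSR,SLAF	TGW	B59
S42	IR58025A x KMR-3R	RIL	24	1082	SNP	TGW	B47
S43	Teqing x IRBB lines, Zhenshan 97 x Milyang 46, Xieqingzao/Milyang 46	RIL	446	654	SSR	SF,GNP	B70
S44	W303 x Nipponbare	F2	166	185	SSR	TGW	B24
S45	Huanghuazhan x Jizi 1560	RIL	208	208	SSR,InDel	SF,PN,GNP	B52
S46	PDK Shriram x Heera	RIL	188	133	SSR,SNP	SF	B85
S47	166s x 14s	F2	174	79	SSR	GNP,TGW	B9
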