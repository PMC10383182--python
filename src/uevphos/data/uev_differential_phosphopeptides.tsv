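comparison	direction	gene	peptide	site	p_value
DN/DM	up	ACSA	SWSPPPEVSR	S3	0.00240942
DN/DM	up	AMNLS	RLSLVPK	S3	0.01164248
DN/DM	up	BAIP2	AFPAQTASGFK	T6	0.003610772
DN/DM	up	BAIP2	LSDSYSNTLPVR	T8	0.00927998
DN/DM	up	CHSP1	GNVVPSPLPTR	S6	0.011014319
DN/DM	up	ES8L1	SLNSTPPPPPAPAPAPPPALAR	T5	0.031333883
DN/DM	up	FIBA	PGSTGTWNPGSSER	S11	0.003771194
DN/DM	up	GSK3B	GEPNVSYICSR	Y7	0.028989048
DN/DM	up	GPC5B	TAGFPNGSLGK	S8	0.022155551
DN/DM	up	GPC5C	ATANSQVMGSANSTLR	S13	0.010074399
DN/DM	up	K1C13	MIGFPSSAGSVSPR	S12	0.003025495
DN/DM	up	KIF12	SPGQVLPPH	S1	1.37e-10
DN/DM	up	MAP1A	TLPQEPGK	T1	0.00176674
DN/DM	up	MILK1	SPVPSPGSSSPQLQVK	S10	0.022496032
DN/DM	up	MY15B	AVPSPPPPPIVK	S4	0.001997071
DN/DM	up	NAT8L	MSVDSRFR	S5	0.029409743
DN/DM	up	NPT2A	LGSPAVSPLPVR	S7	0.002418861
DN/DM	up	PDZ1I	YSSMAASFR	S7	0.004247949
DN/DM	up	SHAN2	RAPSPVVSPTEMNK	S4	0.035395595
DN/DM	up	VINEX	AIETRLPSPK	T4	0.003764395
DN/DM	up	VP37D	SAQPAPTSAADPPK	S1	0.023114006
DN/DM	up	YG015	IELSYNK	Y5	0.002020309
DN/DM	up	ZNF25	SHFIIHQR	S1	0.003312002
DN/DM	down	AQP2	RQSVELHSPQSLPR	S3	0.001562435
DN/DM	down	AQP2	RRQSVELHSPQSLPR	S4	0.001865546
DN/DM	down	CAN7L	INSAHGSDKSK	S3	0.005547201
DN/DM	down	CF170	KWMHAHYSR	S8	8.55e-6
DN/DM	down	CHM4C	LPNVPSSSLPAQPNR	S8	0.03478666
DN/DM	down	CI169	NPYAHISIPR	S7	0.014805139
DN/DM	down	CK052	TLKPQPQQLQQNLPK	T1	0.015894205
DN/DM	down	CP250	QSESLSELITLR	S2	0.007130084
DN/DM	down	CSPP1	QPSPIVPALQNK	S3	0.000997041
DN/DM	down	EPS8	APAPAPPGTVTQVDVR	T9	0.001709885
DN/DM	down	EPS8	KGPGEGVLTLR	T9	0.003312002
DN/DM	down	ES8L2	HSPTSEPTPPGDALPPVSSPHTHR	S19	0.041726109
DN/DM	down	EZRI	QLLTLSSELSQAR	T4	3.66e-6
DN/DM	down	GPC5C	VPSEGAYDIILPR	S3	0.00052554
DN/DM	down	ICK	STPGLIPRPPAAQPVHGR	T2	0.021340709
DN/DM	down	IF4E2	TASDQATTARIR	S3	0.019186167
DN/DM	down	LDHA	TPKIVSGK	T1	0.020570378
DN/DM	down	LMNA	SGAQASSTPLSPTRITR	S11	0.00927998
DN/DM	down	MUC1	DTYHPMSEYPTYHTHGR	S7	0.035395595
DN/DM	down	RAB10	FHTITTSYYR	T3	0.006517696
DN/DM	down	RAI3	AHAWPSPYKDYEVK	S6	0.01798913
DN/DM	down	SARG	ANSALTPPKPESGLTLQESNTPGLR	T6	0.019581944
DN/DM	down	SHS6L	TPNLDWR	T1	0.000684591
DN/DM	down	TRPV5	ASLALPTSSLSR	S11	0.00176674
DN/NC	up	ACSA	SWSPPPEVSR	S3	0.00240942
DN/NC	up	AMNLS	RLSLVPK	S3	0.01164248
DN/NC	up	BAIP2	AFPAQTASGFK	T6	0.003610772
DN/NC	up	BAIP2	LSDSYSNTLPVR	T8	0.00927998
DN/NC	up	CHSP1	GNVVPSPLPTR	S6	0.011014319
DN/NC	up	ES8L1	SLNSTPPPPPAPAPAPPPALAR	T5	0.031333883
DN/NC	up	FIBA	PGSTGTWNPGSSER	S11	0.003771194
DN/NC	up	GSK3B	GEPNVSYICSR	Y7	0.028989048
DN/NC	up	GPC5B	TAGFPNGSLGK	S8	0.022155551
DN/NC	up	GPC5C	ATANSQVMGSANSTLR	S13	0.010074399
DN/NC	up	K1C13	MIGFPSSAGSVSPR	S12	0.003025495
DN/NC	up	KIF12	SPGQVLPPH	S1	1.37e-10
DN/NC	up	MAP1A	TLPQEPGK	T1	0.00176674
DN/NC	up	MILK1	SPVPSPGSSSPQLQVK	S10	0.022496032
DN/NC	up	MY15B	AVPSPPPPPIVK	S4	0.001997071
DN/NC	up	NAT8L	MSVDSRFR	S5	0.029409743
DN/NC	up	NPT2A	LGSPAVSPLPVR	S7	0.002418861
DN/NC	up	PDZ1I	YSSMAASFR	S7	0.004247949
DN/NC	up	SHAN2	RAPSPVVSPTEMNK	S4	0.035395595
DN/NC	up	VINEX	AIETRLPSPK	T4	0.003764395
DN/NC	up	VP37D	SAQPAPTSAADPPK	S1	0.023114006
DN/NC	up	YG015	IELSYNK	Y5	0.002020309
DN/NC	up	ZNF25	SHFIIHQR	S1	0.003312002
DN/NC	down	AQP2	RQSVELHSPQSLPR	S3	0.001562435
DN/NC	down	AQP2	RRQSVELHSPQSLPR	S4	0.001865546
DN/NC	down	CAN7L	INSAHGSDKSK	S3	0.005547201
DN/NC	down	CF170	KWMHAHYSR	S8	8.55e-6
DN/NC	down	CHM4C	LPNVPSSSLPAQPNR	S8	0.03478666
DN/NC	down	CI169	NPYAHISIPR	S7	0.014805139
DN/NC	down	CK052	TLKPQPQQLQQNLPK	T1	0.015894205
DN/NC	down	CP250	QSESLSELITLR	S2	0.007130084
DN/NC	down	CSPP1	QPSPIVPALQNK	S3	0.000997041
DN/NC	down	EPS8	APAPAPPGTVTQVDVR	T9	0.001709885
DN/NC	down	EPS8	KGPGEGVLTLR	T9	0.003312002
DN/NC	down	ES8L2	HSPTSEPTPPGDALPPVSSPHTHR	S19	0.041726109
DN/NC	down	EZRI	QLLTLSSELSQAR	T4	3.66e-6
DN/NC	down	GPC5C	VPSEGAYDIILPR	S3	0.00052554
DN/NC	down	ICK	STPGLIPRPPAAQPVHGR	T2	0.021340709
DN/NC	down	IF4E2	TASDQATTARIR	S3	0.019186167
DN/NC	down	LDHA	TPKIVSGK	T1	0.020570378
DN/NC	down	LMNA	SGAQASSTPLSPTRITR	S11	0.00927998
DN/NC	down	MUC1	DTYHPMSEYPTYHTHGR	S7	0.035395595
DN/NC	down	RAB10	FHTITTSYYR	T3	0.006517696
DN/NC	down	RAI3	AHAWPSPYKDYEVK	S6	0.01798913
DN/NC	down	SARG	ANSALTPPKPESGLTLQESNTPGLR	T6	0.019581944
DN/NC	down	SHS6L	TPNLDWR	T1	0.000684591
DN/NC	down	TRPV5	ASLALPTSSLSR	S11	0.00176674
DM/NC	up	AQP2	RQSVELHSPQSLPR	S3	0.00351656
DM/NC	up	AQP2	RRQSVELHSPQSLPR	S4	0.003246139
DM/NC	up	CAN7L	INSAHGSDKSK	S3	0.007011764
DM/NC	up	CF170	KWMHAHYSR	S8	3.21e-6
DM/NC	up	CI169	NPYAHISIPR	S7	0.003453563
DM/NC	up	CP250	QSESLSELITLR	S2	0.00612397
DM/NC	up	CSPP1	QPSPIVPALQNK	S3	0.004669614
DM/NC	up	EPS8	APAPAPPGTVTQVDVR	T9	0.000581478
DM/NC	up	EPS8	KGPGEGVLTLR	T9	0.00052707
DM/NC	up	ES8L1	AAGEGLLTLR	T8	1.84e-5
DM/NC	up	ES8L1	SLNSTPPPPPAPAPAPPPALAR	S4	0.014008085
DM/NC	up	ES8L2	HSPTSEPTPPGDALPPVSSPHTHR	S19	0.040008069
DM/NC	up	EZRI	QLLTLSSELSQAR	T4	8.73e-6
DM/NC	up	GPC5C	GVGYETILK	T6	1.68e-8
DM/NC	up	GPC5C	VPSEGAYDIILPR	S3	0.000326668
DM/NC	up	GSK3B	GEPNVSYICSR	Y7	0.008989048
DM/NC	up	HSPB1	GPSWDPFR	S3	0.047463946
DM/NC	up	ICK	STPGLIPRPPAAQPVHGR	T2	0.006484348
DM/NC	up	LDHA	TPKIVSGK	T1	0.020666271
DM/NC	up	MUC1	DTYHPMSEYPTYHTHGR	T11	0.025694245
DM/NC	up	RAB10	FHTITTSYYR	T3	0.005397277
DM/NC	up	SARG	ANSALTPPKPESGLTLQESNTPGLR	T6	0.041546421
DM/NC	up	SHS6L	TPNLDWR	T1	0.003375752
DM/NC	up	TRRAP	LEPAFLSGLR	S7	0.043482561
DM/NC	up	YG015	IELSYNK	Y5	0.001729708
DM/NC	down	AMNLS	RLSLVPK	S3	0.014008085
DM/NC	down	BAIP2	AFPAQTASGFK	T6	0.00053512
DM/NC	down	C2D1A	GPASTPTYSPAPTQPAPR	S9	1.85e-11
DM/NC	down	DYRK2	KPSAAAPAAYPTGR	S3	0.001809625
DM/NC	down	G3P	GALQNIIPASTGAAK	S10	0.022036915
DM/NC	down	GPC5B	TAGFPNGSLGK	S8	0.011034256
DM/NC	down	IF4E2	TASDQATTARIR	S3	0.012911956
DM/NC	down	IST1	NISSAQIVGPGPKPEASAK	S3	2.28e-5
DM/NC	down	K1522	ASPVPAPSSGLHAAVR	S2	0.017621205
DM/NC	down	KIF12	DLLSLGSPR	S7	0.000979657
DM/NC	down	KIF12	SPGQVLPPH	S1	1.17e-10
DM/NC	down	LMNA	SGAQASSTPLSPTRITR	S11	0.033756475
DM/NC	down	MAP1A	TLPQEPGK	T1	0.037174836
DM/NC	down	MILK1	SPVPSPGSSSPQLQVK	S10	0.002110621
DM/NC	down	MY15B	AVPSPPPPPIVK	S4	0.02828527
DM/NC	down	NPT2A	LGSPAVSPLPVR	S7	0.00017686
DM/NC	down	SL9A3	RGSLAFIR	S3	0.031611131
DM/NC	down	TRPV5	ASLALPTSSLSR	S11	0.000897584
DM/NC	down	VP37D	SAQPAPTSAADPPK	S1	0.004954683
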