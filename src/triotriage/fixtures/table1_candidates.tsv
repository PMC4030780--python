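proband_id	gene	mode	variant	consequence	note
F2	GRIN2A	de_novo	16:9943200:C:T	non_synonymous	.
F3	PPFIBP2	de_novo	11:7650200:C:T	non_synonymous	mz_shared
F16	PPFIBP2	de_novo	11:7650200:C:T	non_synonymous	mz_shared
F6	C11orf41	de_novo	11:33680500:G:A	non_synonymous	.
F6	NF1	de_novo	17:29550300:G:A	non_synonymous	.
F6	SMARCC2	de_novo	12:56565800:C:T	stop_gained	.
F6	ZHX3	de_novo	20:39807100:G:A	synonymous	.
F7	UNC80	de_novo	2:210650400:C:T	stop_gained	.
F7	WFDC8	de_novo	20:44288600:A:G	non_synonymous	.
F8	CD244	de_novo	1:160800900:G:C	stop_gained	.
F9	PARD3B	de_novo	2:205410313:G:C	non_synonymous	mosaic
F10	ATP6V1B2	de_novo	8:20054700:T:C	non_synonymous	.
F10	SEMA4D	de_novo	9:92001100:C:A	non_synonymous	second_hit_maternal_missense
F14	KCTD8	de_novo	4:44449200:A:C	non_synonymous	.
F14	STX12	de_novo	1:28099300:G:T	essential_splice_site	.
F15	DOCK1	de_novo	10:128594400:C:G	non_synonymous	.
F18	ABCB9	de_novo	12:123420500:G:A	non_synonymous	.
F18	FAM3D	de_novo	3:58620600:A:T	non_synonymous	.
F19	DNAJC13	de_novo	3:132136700:C:T	synonymous	.
F19	NLRP1	de_novo	17:5424800:G:A	non_synonymous	.
F19	PARD3B	de_novo	2:205410731:G:A	non_synonymous	.
F20	COL2A1	de_novo	12:48379990:C:A	non_synonymous	.
F22	TACR2	de_novo	10:71172900:A:G	non_synonymous	.
F23	FGFR3	de_novo	4:1803564:A:G	non_synonymous	.
F25	PNLIPRP1	de_novo	10:118349200:C:T	non_synonymous	.
F25	SMARCC1	de_novo	3:47699300:T:C	non_synonymous	.
F26	KDM5B	de_novo	1:202712400:G:T	non_synonymous	.
F26	STAU2	de_novo	8:74459500:A:G	non_synonymous	.
F27	C2orf40	de_novo	2:106762600:G:A	non_synonymous	.
F27	INSC	de_novo	11:15136000:C:G	non_synonymous	.
F28	PPP6R1	de_novo	19:55729400:C:T	non_synonymous	.
F31	FMNL3	de_novo	12:50033100:G:C	non_synonymous	.
F33	SEC31B	de_novo	10:102269300:G:T	non_synonymous	mosaic
F33	EGFL6	de_novo	X:13586500:C:T	synonymous	.
F1	HEPHL1	compound_het	.	.	.
F1	PRKDC	compound_het	.	.	.
F1	ZNF44	compound_het	.	.	.
F2	FAM83E	compound_het	.	.	.
F2	KIAA1239	compound_het	.	.	.
F2	KIAA1755	compound_het	.	.	.
F2	LAMA5	compound_het	.	.	.
F2	MIA3	compound_het	.	.	.
F3	C16orf91	compound_het	.	.	.
F3	C9orf79	compound_het	.	.	.
F3	CCDC144NL	compound_het	.	.	.
F3	NHSL1	compound_het	.	.	.
F5	DLC1	compound_het	.	.	.
F5	TTN	compound_het	.	.	.
F6	FAM188B	compound_het	.	.	.
F6	RELN	compound_het	.	.	.
F6	RERE	compound_het	.	.	.
F7	MUC16	compound_het	.	.	.
F7	TSC22D1	compound_het	.	.	.
F7	TTN	compound_het	.	.	.
F8	LY75-CD302	compound_het	.	.	.
F8	TTN	compound_het	.	.	.
F8	WDR59	compound_het	.	.	.
F9	ABCA13	compound_het	.	.	.
F9	COL6A6	compound_het	.	.	.
F9	GNAS	compound_het	.	.	.
F9	KIAA1462	compound_het	.	.	.
F9	MUC17	compound_het	.	.	.
F9	SRRM2	compound_het	.	.	.
F9	TRPM8	compound_het	.	.	.
F10	C19orf28	compound_het	.	.	.
F10	CDHR1	compound_het	.	.	.
F10	DNAH10	compound_het	.	.	.
F10	MACF1	compound_het	.	.	.
F11	REST	compound_het	.	.	.
F12	FRG1B	compound_het	.	.	.
F12	TTN	compound_het	.	.	.
F12	ZNF451	compound_het	.	.	.
F13	FRAS1	compound_het	.	.	.
F13	SPTBN5	compound_het	.	.	.
F13	TPO	compound_het	.	.	.
F14	ADNP	compound_het	.	.	.
F14	ANO7	compound_het	.	.	.
F14	CENPF	compound_het	.	.	.
F14	TDRD6	compound_het	.	.	.
F15	ABLIM3	compound_het	.	.	.
F15	VCAN	compound_het	.	.	.
F16	C16orf91	compound_het	.	.	.
F16	C9orf79	compound_het	.	.	.
F16	CCDC144NL	compound_het	.	.	.
F16	NHSL1	compound_het	.	.	.
F17	ABCA3	compound_het	.	.	.
F17	AKAP11	compound_het	.	.	.
F17	DEPDC1	compound_het	.	.	.
F17	PAFAH2	compound_het	.	.	.
F17	POM121C	compound_het	.	.	.
F18	PCCB	compound_het	.	.	.
F18	TTN	compound_het	.	.	.
F18	ZFHX3	compound_het	.	.	.
F19	AHNAK2	compound_het	.	.	.
F19	C20orf90	compound_het	.	.	.
F19	CD163L1	compound_het	.	.	.
F19	DNAH1	compound_het	.	.	.
F19	DNAH5	compound_het	.	.	.
F19	DNAH6	compound_het	.	.	.
F19	FSTL4	compound_het	.	.	.
F19	PHLPP2	compound_het	.	.	.
F20	CHD7	compound_het	.	.	.
F20	EPB41L2	compound_het	.	.	.
F20	GPR98	compound_het	.	.	.
F20	VPS13D	compound_het	.	.	.
F21	CACNA1H	compound_het	.	.	.
F21	PKHD1	compound_het	.	.	.
F22	DECR1	compound_het	.	.	.
F22	DUOXA1	compound_het	.	.	.
F22	NEB	compound_het	.	.	.
F22	VPS13C	compound_het	.	.	.
F23	C1orf129	compound_het	.	.	.
F23	SHANK2	compound_het	.	.	.
F23	TTN	compound_het	.	.	.
F25	HSPG2	compound_het	.	.	.
F25	IQGAP3	compound_het	.	.	.
F26	GNRHR2	compound_het	.	.	.
F28	CYP24A1	compound_het	.	.	.
F28	KIAA1109	compound_het	.	.	.
F28	KIAA1609	compound_het	.	.	.
F28	SLC39A11	compound_het	.	.	.
F29	ABCA13	compound_het	.	.	.
F29	MCF2L2	compound_het	.	.	.
F29	NLRP12	compound_het	.	.	.
F29	POM121C	compound_het	.	.	.
F29	TTN	compound_het	.	.	.
F29	ZNF831	compound_het	.	.	.
F31	FAH	compound_het	.	.	.
F33	AGRN	compound_het	.	.	.
F33	NUDT19	compound_het	.	.	.
F6	AXL	homozygous	.	.	.
F19	ADAD2	homozygous	.	.	.
F19	PCNT	homozygous	.	.	.
F21	KIF26A	homozygous	.	.	.
F22	PCDHB7	homozygous	.	.	.
F23	GFM2	homozygous	.	.	.
F29	TTN	homozygous	.	.	.
F1	BCORL1	hemizygous	.	.	.
F1	FAM47A	hemizygous	.	.	.
F1	KCNE1L	hemizygous	.	.	.
F1	MAGEA6	hemizygous	.	.	.
F1	ZCCHC12	hemizygous	.	.	.
F3	CCDC22	hemizygous	.	.	.
F3	SHROOM2	hemizygous	.	.	.
F5	FAM70A	hemizygous	.	.	.
F5	FTHL17	hemizygous	.	.	.
F5	GPR112	hemizygous	.	.	.
F5	PCDH19	hemizygous	.	.	.
F5	RBMXL3	hemizygous	.	.	.
F5	WDR44	hemizygous	.	.	.
F8	PLXNB3	hemizygous	.	.	.
F8	RBBP7	hemizygous	.	.	.
F8	SRPX2	hemizygous	.	.	.
F9	ATP2B3	hemizygous	.	.	.
F9	CCDC22	hemizygous	.	.	.
F11	CITED1	hemizygous	.	.	.
F11	MXRA5	hemizygous	.	.	.
F11	NR0B1	hemizygous	.	.	.
F13	ALG13	hemizygous	.	.	.
F13	DDX26B	hemizygous	.	.	.
F13	MAP7D3	hemizygous	.	.	.
F13	TLR7	hemizygous	.	.	.
F16	SHROOM2	hemizygous	.	.	.
F18	CXorf57	hemizygous	.	.	.
F18	DUSP21	hemizygous	.	.	.
F18	F9	hemizygous	.	.	.
F18	FOXR2	hemizygous	.	.	.
F18	HS6ST2	hemizygous	.	.	.
F18	NKAP	hemizygous	.	.	.
F18	RBMX2	hemizygous	.	.	.
F19	COL4A6	hemizygous	.	.	.
F19	GYG2	hemizygous	.	.	.
F19	PNMA3	hemizygous	.	.	.
F19	SATL1	hemizygous	.	.	.
F19	SHROOM2	hemizygous	.	.	.
F20	FAM58A	hemizygous	.	.	.
F20	MTCP1NB	hemizygous	.	.	.
F20	PLXNA3	hemizygous	.	.	.
F20	SLC10A3	hemizygous	.	.	.
F21	ARMCX2	hemizygous	.	.	.
F21	EDA2R	hemizygous	.	.	.
F21	HTATSF1	hemizygous	.	.	.
F21	MAP7D3	hemizygous	.	.	.
F21	MTMR8	hemizygous	.	.	.
F21	MXRA5	hemizygous	.	.	.
F22	MAP7D3	hemizygous	.	.	.
F23	MAP3K15	hemizygous	.	.	.
F23	MAP7D3	hemizygous	.	.	.
F25	BCOR	hemizygous	.	.	.
F25	RAB40A	hemizygous	.	.	.
F25	USP26	hemizygous	.	.	.
F26	HTATSF1	hemizygous	.	.	.
F26	MTMR1	hemizygous	.	.	.
F26	PIR	hemizygous	.	.	.
F3	H2BFM	cnv_x_linked	X:103030000:103100000:duplication	.	cnv_group=CNV_F3
F3	H2BFWT	cnv_x_linked	X:103030000:103100000:duplication	.	cnv_group=CNV_F3
F14	GPM6B	cnv_de_novo	X:13770686:13791294:deletion	.	cnv_group=CNV_F14
F14	OFD1	cnv_de_novo	X:13770686:13791294:deletion	.	cnv_group=CNV_F14
F19	SSX3	cnv_x_linked	X:48205000:48300000:duplication	.	cnv_group=CNV_F19
F19	SSX4	cnv_x_linked	X:48205000:48300000:duplication	.	cnv_group=CNV_F19
F19	SSX4B	cnv_x_linked	X:48205000:48300000:duplication	.	cnv_group=CNV_F19
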