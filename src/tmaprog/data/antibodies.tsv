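code	antibody	localization	observed
X01	Acetyl H3(lys9)	N	N
X02	APC	C	C, M
X03	Bax	C	C
X04	c-Fos	N	N
X05	c-Met	M	C, M
X06	CD24	M	C, M
X07	CD44	C, M	C, M
X08	CDC25B	C, N	N
X09	c-Jun	N	C, N
X10	c-K-Ras	C	C
X11	c-Myc	N	C, N
X12	c-N-Ras	C	C
X13	Cytochrome C	C	C
X14	Cyclin D1	N	N
X15	Cyclin E	N	N
X16	DCC	N	C
X17	Dimethyl histone H3 (lys4)	N	N
X18	Dimethyl histone H3 (lys9)	N	N
X19	Dimethyl histone H4 (arg3)	N	N
X20	Dnmt1	N	C, N
X21	E-cadherin	M	C
X22	E2F-1	N	C, N
X23	FHIT	C	C
X24	Histone H1 (B419)	N	N
X25	Histone H3 (dimethyl K9)	N	N
X27	MLH1	N	N
X28	MDM2	N	N
X31	p16	C, N	C, N
X32	p18	N	C, N
X33	p21	N	C, N
X34	p27	C, N	C, N
X35	p53	N	N
X36	p63	N	C, N
X37	p130	N	N
X38	PTEN	C, M	C, M
X39	Rb	N	N
X40	RAR-b	C, N	C, N
X41	Survivin	C, N	C, N
X42	Telomerase	N	N
X43	TGF-a	C, M	C, M
X44	TGF-b	C	C, M
X45	TIMP-3	C	C, M
X46	VEGF	C, M	C, M
X47	VEGFR1	C, M	C, M, N
X49	Notch	C, M, N	C, M, N
X50	Cyclin E (SC-198)	N	C, N
X51	CD31	M	C, N
X52	Id4	C	C, M
X53	pGP	M	C, M
X54	SMA	C	C, N
X55	MIB-1	N	N
X56	SOX-2	N	C, N
X57	Nestin	C	C
X58	Musashi	C	C, N
X60	SMA (Abcam)	C	C
X61	p-p70 S6 kinase (Thr421/Ser424)	C	C, N
X63	p-AKT (Ser473)	C, N	C, N
X64	Akt	N	C, N
X65	CD133	M	C, M
X66	PDGF-A	C, M	C, N
X67	PDGFR-a	C, M	C, M
X68	p-PDGFR-a (Tyr720)	C, M	C, M
X69	PDGF-B	C, M	C
X70	PDGFR-b	C, M	C, M
X71	p-PDGFR-b (Tyr1021)	M	C, M
X72	VEGF (SC-152)	C, M	C
X73	VEGFR2	C, M	C, M
X74	p-VEGFR2 (Tyr1175)	C, M	C, M
X75	p-VEGFR2/3	C, M	C, M
X76	EGF	C, M	C, M, N
X77	EGFR	M	C, M
X78	p-EGFR (Tyr1173)	C, M	C, M
X79	MMP2	C, M	C, M
X80	MMP9	C, M	C
X81	Cleaved caspase-3	C, N	C, N
X82	Wild-type EGFR	M	C, M
X83	EGFR vIII	C, M	C, M
X84	Notch (ab27526)	C, M, N	C, M, N
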