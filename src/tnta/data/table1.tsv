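toxin_family	toxin_xref	toxin_superfamily	antitoxin_family	antitoxin_xref	antitoxin_superfamily	resolvase_type	subgroup	configuration	transposons	nb	notes
ParE	PF05016	RelE/ParE	ParD	4Q2U_C	RelB/ParD	R	Tn3000	<T <A tnpR> tnpA>	Tn5501 (JN648090.1); Tn5501.1 (CP016447.1); Tn5501.3 (GQ983559.1); Tn5501.4 (KY206932.1); Tn5501.5 (EF628291.1); Tn5501.6 (MF487840.1); Tn5501.7 (CP021651.1); Tn5501.8 (KC771559); Tn5501.9 (AJ863570.1); Tn5501.10 (MH053445); Tn5501.11 (CP002451)	11	Tn5501.5 carries a mutation truncating its toxin gene; antitoxin intact
ParE	PF05016	RelE/ParE	ParD	4Q2U_C	RelB/ParD	R	Tn4651	<T <A tnpR> tnpA>	TnTsp1 (NC_014154)	1
ParE	PF05016	RelE/ParE	ParD-noDBD	4Q2U_C	ParD-noDBD	I	Tn3	<T <A !res! tnpI> tnpA>	TnBth4 (NZ_CP010092.1); Tn5401 (U03554.1)	2
ParE	PF05016	RelE/ParE	Phd/YeFM	PF02604	Phd/YeFM	R	Tn3000	<tnpR A> T> tnpA>	TnSpu1 (CP017991.1); TnAbapMCR4.3 (CP033872)	2
PIN_3	PF13470	PIN	RHH_6	PF16762	VapB	R	Tn3	<tnpR A> T> tnpA>	Tn1412 (L36547); Tn5044 (Y17691.1); Tn5046 (Y18360.1); Tn5563a (KJ920395.1); Tn5563a.1 (CP028162); Tn5563a.2 (CP028567); TnThsp9 (FP475957.1); TnXc4 (CP009039.1); TnXc5 (Z73593); TnXc4.1 (CP011958.1); TnXc4.2 (CP023287); TnXc4.3 (CP020887.1)	12
PIN_3	PF13470	PIN	RHH_6	PF16762	VapB	S/T	Tn4651	<tnpT tnpS> A> T> tnpA>	TnHdN1 (FP929140.1)	1
Gp49	PF05973	RelE/ParE	HTH_37	PF13744	HigA	R	Tn3000	<A <T tnpR> tnpA>	Tn4662a (NC_014124.1); Tn4662a.1 (AY831462.1); TnDsu1 (NC_016616.1); TnPpupPGH1 (Y09450.1); Tn5501.12 (CP017294.1)	5
Gp49	PF05973	RelE/ParE	HTH_37	PF13744	HigA	R	Tn4651	T> A> tnpR> tnpA>	TnPosp1 (CP000316.1)	1
Gp49	PF05973	RelE/ParE	HTH	5TN0_A	HigA	R	Tn163	T> A> <tnpR tnpA>	TnSku1 (CP002358.1)	1
PIN	PF01850	PIN	Phd/YeFM	PF02604	Phd/YeFM	R	Tn163	<T <A <X tnpR> tnpA>	TnAmu2 (NC_015188.1)	1	configuration normalized: source table prints a dual-marker tnpR token; text reads antitoxin and tnpR as divergent
PIN	PF01850	PIN	AbrB	2MRN_A	AbrB/MazE	R	Tn3000	<T <A tnpR> tnpA>	TnPsy42 (KX009060.1)	1
HEPN	5YEP_B	HEPN	Mnt	5YEP_A	Mnt	R	Tn21	<tnpR <T <A tnpA>	TnSod9 (NC_004349)	1
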