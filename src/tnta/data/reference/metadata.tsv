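id	role	family	superfamily	subgroup	notes
TNPA_TN3_SYN	transposase	.	.	Tn3	synthetic exemplar
TNPA_TN21_SYN	transposase	.	.	Tn21	synthetic exemplar
TNPA_TN163_SYN	transposase	.	.	Tn163	synthetic exemplar
TNPA_IS1071_SYN	transposase	.	.	IS1071	synthetic exemplar
TNPA_IS3000_SYN	transposase	.	.	IS3000	synthetic exemplar
TNPA_TN4430_SYN	transposase	.	.	Tn4430	synthetic exemplar
TNPA_TN4651_SYN	transposase	.	.	Tn4651	synthetic exemplar
TNPA_TN3000_SYN	transposase	.	.	Tn3000	synthetic exemplar
TNPR_SYN	resolvase_S	.	.	.	synthetic exemplar
TNPI_SYN	resolvase_Y	.	.	.	synthetic exemplar
TNPS_SYN	resolvase_Y_het	.	.	.	synthetic exemplar
TNPT_SYN	helper	.	.	.	synthetic exemplar
TOX_PARE_1_SYN	toxin	ParE	RelE/ParE	.	synthetic exemplar
TOX_PARE_2_SYN	toxin	ParE	RelE/ParE	.	synthetic exemplar, 65% variant of _1
TOX_PIN_3_1_SYN	toxin	PIN_3	PIN	.	synthetic exemplar
TOX_PIN_3_2_SYN	toxin	PIN_3	PIN	.	synthetic exemplar, 65% variant of _1
TOX_GP49_1_SYN	toxin	Gp49	RelE/ParE	.	synthetic exemplar
TOX_GP49_2_SYN	toxin	Gp49	RelE/ParE	.	synthetic exemplar, 65% variant of _1
TOX_PIN_1_SYN	toxin	PIN	PIN	.	synthetic exemplar
TOX_PIN_2_SYN	toxin	PIN	PIN	.	synthetic exemplar, 65% variant of _1
TOX_HEPN_1_SYN	toxin	HEPN	HEPN	.	synthetic exemplar
TOX_HEPN_2_SYN	toxin	HEPN	HEPN	.	synthetic exemplar, 65% variant of _1
AT_PARD_1_SYN	antitoxin	ParD	RelB/ParD	.	synthetic exemplar
AT_PARD_2_SYN	antitoxin	ParD	RelB/ParD	.	synthetic exemplar, 65% variant of _1
AT_PARDNODBD_1_SYN	antitoxin	ParD-noDBD	ParD-noDBD	.	synthetic exemplar
AT_PARDNODBD_2_SYN	antitoxin	ParD-noDBD	ParD-noDBD	.	synthetic exemplar, 65% variant of _1
AT_PHDYEFM_1_SYN	antitoxin	Phd/YeFM	Phd/YeFM	.	synthetic exemplar
AT_PHDYEFM_2_SYN	antitoxin	Phd/YeFM	Phd/YeFM	.	synthetic exemplar, 65% variant of _1
AT_RHH_6_1_SYN	antitoxin	RHH_6	VapB	.	synthetic exemplar
AT_RHH_6_2_SYN	antitoxin	RHH_6	VapB	.	synthetic exemplar, 65% variant of _1
AT_HTH_37_1_SYN	antitoxin	HTH_37	HigA	.	synthetic exemplar
AT_HTH_37_2_SYN	antitoxin	HTH_37	HigA	.	synthetic exemplar, 65% variant of _1
AT_HTH_1_SYN	antitoxin	HTH	HigA	.	synthetic exemplar
AT_HTH_2_SYN	antitoxin	HTH	HigA	.	synthetic exemplar, 65% variant of _1
AT_ABRB_1_SYN	antitoxin	AbrB	AbrB/MazE	.	synthetic exemplar
AT_ABRB_2_SYN	antitoxin	AbrB	AbrB/MazE	.	synthetic exemplar, 65% variant of _1
AT_MNT_1_SYN	antitoxin	Mnt	Mnt	.	synthetic exemplar
AT_MNT_2_SYN	antitoxin	Mnt	Mnt	.	synthetic exemplar, 65% variant of _1
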