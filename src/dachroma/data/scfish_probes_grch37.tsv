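name	region	position_class	anchor	call	locus
3.3_1p36	chr1:1,171,789–1,175,143	intergenic	false	EA	.
XDH_tel9263	chr2:31,545,815–31,547,924	intergenic	false	DA	XDH
XDH_tel2386	chr2:31,551,816–31,554,801	intergenic	false	DA	XDH
XDH_IVS30-IVS27	chr2:31,568,769–31,571,269	genic	true	DA	XDH
ZNF385D_cen640649	chr3:22,433,351–22,436,333	intergenic	true	DA	HMGB1P5
ZNF385D_cen678130	chr3:22,470,832–22,473,082	intergenic	false	DA	HMGB1P5
FGF6_tel4492	chr12:4,537,157–4,538,816	intergenic	true	DA	FGF6
FGF6_IVS2	chr12:4,549,776–4,553,205	genic	false	DA	FGF6
DUOX1_IVS1-IVS3	chr15: 45,422,890–45,424,597	genic	false	DA	DUOX1
TPM1_IVS5-IVS8	chr15:63,353,573-63,355,980	genic	false	DA	TPM1
TPM1_IVS8	chr15:63,357,346–63,360,645	genic	true	DA	TPM1
TPM1_tel3200	chr15:63,367,314–63,369,607	intergenic	false	DA	TPM1
SCAMP2_IVS7-IVS4	chr15:75,142,349–75,145,350	genic	true	DA	COX5A
SCAMP2_IVS1	chr15:75,161,783–75,163,308	genic	false	DA	COX5A
COX5A_tel20181	chr15:75,250,595–75,252,319	intergenic	false	DA	COX5A
RBM38_tel25076	chr20:56,009,465–56,011,485	intergenic	false	DA	HMGB1P1
CTCFL_cen34302	chr20:56,033,167–56,036,719	intergenic	true	DA	HMGB1P1
PCK1_cen13065	chr20:56,119,569–56,123,101	intergenic	false	DA	HMGB1P1
PCK1_cen209-IVS6	chr20:56,135,957–56,139,048	genic	false	DA	HMGB1P1
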