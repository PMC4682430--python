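accession	gene_id	description	meth_S	meth_R	expr_S	expr_R
FG345845	Bv_39660_duks.t1	HXXXD-type acyl-transferase-like protein	-0.67	1.16	1.49	-1.62
BQ589458	NA	No significant hit	0.53	-0.52	0.85	-0.66
BQ586261	Bv6_125340_epqo.t1	Germin-like protein 5 (GLP5/PDGLP1)	0.72	-0.42	0.30	-0.75
FG343208	Bv7u_181680_otyh.t1	Beta-amyrin synthase	1.15	-0.04	-0.61	0.93
BQ582907	Bv7_160760_mmcw.t1	Carotenoid epsilon-ring hydroxylase (LUT1/CYP97C1)	1.22	-0.07	1.01	-0.89
FG344953	Bv3_049870_xxoz.t1	1-Aminocyclopropane-1-carboxylate oxidase-like protein 9	1.40	0.17	0.63	-0.41
BQ582428	Bv4u_091120_gpyr.t1	RNA polymerase II transcription mediator activity	1.43	0.21	-1.01	0.88
CF543348	NA	No significant hit	1.59	0.53	-2.36	2.26
CK136737	Bv4_074360_ejeh.t1	Cystatin 6 (CYSB)	1.69	0.57	0.99	-0.93
BQ589845	Bv4u_091720_azjm.t1	No significant hit	1.89	0.68	-2.35	2.03
FG345537	Bv9_208140_cjcm.t1	No significant hit	1.99	0.29	-1.01	1.60
BQ489455	Bv7_169260_ewnm.t1	ATPase E1-E2 type family protein	2.13	0.63	-2.59	1.44
BQ585496	Bv2_042300_ners.t1	SPX domain-containing protein 4 (SPX4)	2.48	1.16	0.35	-0.68
BQ488791	NA	No significant hit	2.52	1.43	-0.45	1.03
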