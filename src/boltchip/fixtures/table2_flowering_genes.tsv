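accession	gene	probe_group_start	probe_group_end	n_probes	meth_S	meth_R	expr_S	expr_R
HR807147	BvRNMTb	0	260	2	1.64	0.58	NA	NA
BQ592158	BvFVE	60	120	1	1.60	0.63	0.58	0.00
HM448911	BvFT2	0	240	5	2.25	0.94	NA	NA
HM448911	BvFT2	210	630	9	-2.25	-2.24	NA	NA
HM448911	BvFT2	1080	2070	17	1.42	0.75	NA	NA
HM448911	BvFT2	2820	4260	6	1.31	0.41	NA	NA
HM448909	BvFT1	60	260	3	1.60	1.39	NA	NA
HM448909	BvFT1	1100	1773	8	1.48	0.59	NA	NA
HM448909	BvFT1	2763	4893	6	0.92	0.28	NA	NA
DQ189214/DQ189215	BvFL1	790	1090	2	1.46	1.00	-0.17	0.30
DQ189214/DQ189215	BvFL1	5950	6130	5	-2.58	-2.56	NA	NA
BQ584677	BvFUL	NA	NA	NA	NA	NA	-0.45	0.55
BQ588867	BvSVP	NA	NA	NA	NA	NA	0.00	-0.65
EU437782	BvCOL1	NA	NA	NA	NA	NA	0.65	0.36
BQ488144	BvAGL24	NA	NA	NA	NA	NA	1.04	-0.75
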