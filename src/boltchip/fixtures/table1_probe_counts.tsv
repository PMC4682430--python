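platform	origin	submitted_label	submitted	designed	filtered	called
transcriptomic	public_database	154 mitochondrial ORFs	154	132	106	2
transcriptomic	public_database	30 023 ORFs from ESTs	30023	28918	21043	159
transcriptomic	public_database	22 candidate genes	22	44	26	3
transcriptomic	cot_fraction	42 004 ORFs	42004	24658	1273	5
transcriptomic	total	Total	72203	53752	22448	169
methylation	public_database	1 mitochondrial genome	1	3688	3211	27
methylation	public_database	29 585 ESTs	29585	185425	14069	110
methylation	public_database	22 candidate genes	22	1426	109	1
methylation	cot_fraction	6231 contigs	6231	36	2185	0
methylation	total	Total	35839	227242	19574	138
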