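line	flowcell	input_fmoles	read_count	bases	n50	file_size_gb
GB-ls-coga4	MIN	16.18	4600000	16590000000	8900	198.7
GB-ls-coga4	FLG	7.7	116590	328250000	9700	3.8
GB-ls-coga4	FLG	7.7	76720	242470000	10090	2.8
GB-ls-coga4	FLG	19.41	224540	347580000	3670	4.2
GB-ls-coga4	FLG	20	34940	87120000	7300	1.0
GB-ls-coga4	FLG	20	155390	268840000	4040	3.1
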