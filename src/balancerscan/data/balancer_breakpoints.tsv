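balancers	aberration	polytene	site	chrom	proximal	distal	printed_delta	predicted_band	disrupts
SM1,SM5,SM6a,CyO	In(2L)Cy	22D1-2	head	2L	NA	NA	NA	22D1	CG11723|TBCD|AIF
SM1,SM5,SM6a,CyO	In(2L)Cy	33F5-34A1	tail	2L	NA	NA	NA	33F4	MRP
SM1,SM5,SM6a,CyO	In(2R)Cy	42A2-3	head	2R	6012459	6012739	280	42A7	Src42A-5prime
SM1,SM5,SM6a,CyO	In(2R)Cy	58A4-58B1	tail	2R	21971918	21972072	-153	58A4	.
SM1,SM5,SM6a	In(2LR)SM1	22A3-22B1	head	2L	1586845	1586840	-4	22A3	haf|CG10869
SM1,SM5,SM6a	In(2LR)SM1	60B-60C	tail	2R	24117046	24117059	-12	60B11	CG3257
SM6a,CyO	In(2LR)O	30E-30F	head	2L	9805575	9805567	-7	30D1	nAChRalpha6
SM6a,CyO	In(2LR)O	50C10-50D1	tail	2R	14067771	14067782	-10	50D4	Prosap
SM5	In(2L)SM5-1	21D1-2	head	2L	675187	675190	4	21E2	ds
SM5	In(2L)SM5-1	36C	tail	2L	16995337	16995336	2	36B6	.
SM5	In(2L)SM5-2	29C-29E	head	2L	NA	NA	NA	29D5-E4	unknown
SM5	In(2L)SM5-2	40F	tail	2L	NA	NA	NA	40F	unknown
SM5	Dp(2;2)SM5	42D	head	2R	NA	6917406	NA	42E1	CG30158
SM5	Dp(2;2)SM5	53C	tail	2R	16682351	16682827	-475	53D1	CG30463
SM5	Dp(2;2)SM5	58F	tail	2R	22689962	22689962	0	59A2	CR44763
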