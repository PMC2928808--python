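rsid	chrom	gene	risk_allele	published_or	in_score
rs10923931	1	NOTCH2	T	1.06	1
rs7578597	2	THADA	T	1.13	1
rs1801282	3	PPARG	C	1.13	1
rs4607103	3	ADAMTS9	C	1.02	1
rs4402960	3	IGF2BP2	T	1.13	1
rs10010131	4	WFS1	G	1.11	1
rs7754840	6	CDKAL1	C	1.20	1
rs864745	7	JAZF1	T	1.20	1
rs13266634	8	SLC30A8	C	1.15	1
rs2383208	9	CDKN2B	A	1.18	1
rs1111875	10	HHEX	C	1.07	1
rs7903146	10	TCF7L2	T	1.36	1
rs12779790	10	CDC123	G	1.10	1
rs2237895	11	KCNQ1	C	1.11	1
rs2237897	11	KCNQ1	C	1.21	1
rs5219	11	KCNJ11	T	1.15	1
rs7961581	12	TSPAN8	C	1.01	1
rs8050136	16	FTO	A	1.02	0
rs4430796	17	HNF1B	G	1.05	1
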