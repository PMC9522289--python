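mir	group	regulation	kd_read_count	wt_read_count	log2_fold_change	padj	host_gene	host_class	refseq_accession	n_cpre	n_ncpre
5009-5p	dem	up	15.423	1.928	1.401	0.0298	AP3S2	protein_coding	NM_005829.5	0	1
3944-3p	dem	up	18.695	2.704	1.269	0.0489	ECHS1	protein_coding	NM_004092.4	0	0
200a-3p	dem	up	133.627	40.315	1.247	0.0313		unknown			
4723-5p	dem	up	6.596	0.000	1.209	0.0421	TMEM199	protein_coding	NM_152464.3	0	1
novel_123	dem	up	902.111	439.949	0.991	0.0001		lncRNA	XR_934960.2	0	4
182-5p	dem	up	206.508	100.765	0.973	0.0013		unknown			
146b-3p	dem	up	165.948	93.492	0.760	0.0284		unknown			
1269b	dem	up	4150.924	3155.166	0.389	0.0199	ARHGAP44	protein_coding	NM_014859.6	1	3
93-5p	dem	down	6222.189	8370.860	-0.418	0.0320	MCM7	protein_coding	NM_005916.5	0	1
17-5p	dem	down	261.926	392.089	-0.559	0.0303		lncRNA	NR_027350.1	2	19
151a-5p	dem	down	177.550	278.509	-0.616	0.0409	PTK2	protein_coding	NM_001352694.2	0	1
30e-5p	dem	down	277.386	456.769	-0.672	0.0327	NFYC	protein_coding	NM_001142588.2	0	0
592	dem	down	66.639	123.369	-0.818	0.0171	GRM8	protein_coding	NM_000845.3	0	2
641	dem	down	26.997	72.951	-1.116	0.0343	AKT2	protein_coding	NM_001626.6	1	2
93-3p	dem	down	22.742	63.801	-1.137	0.0359	MCM7	protein_coding	NM_005916.5	0	1
4742-3p	dem	down	0.000	8.757	-1.199	0.0437	WDR26	protein_coding	NM_025160.7	1	12
4787-3p	dem	down	5.691	25.635	-1.298	0.0401	DOCK3	protein_coding	NM_004947.5	3	2
151b	dem	down	5.847	24.139	-1.342	0.0282	EVL	protein_coding	NM_016337.3	0	0
4745-5p	dem	down	0.000	8.094	-1.363	0.0257	PTBP1	protein_coding	NM_002819.5	1	3
127-3p	dem	down	52.116	235.150	-1.396	0.0235	RTL1	protein_coding	NM_001134888.3	0	0
381-3p	dem	down	53.302	197.874	-1.495	0.0042		lncRNA	NR_104192.1	0	0
125a-5p	control	unregulated	3072.247	3221.872	-0.067	0.7446	SPACA6	protein_coding	NM_001316972.2	0	0
27b-3p	control	unregulated	10073.576	11623.339	-0.203	0.1908	AOPEP	protein_coding	NM_001193329.3	0	1
3184-5p	control	unregulated	62009.295	49324.221	0.321	0.1347	NSRP1	protein_coding	NM_001261467.2	0	3
4473	control	unregulated	436.469	340.640	0.344	0.2021	MLLT3	protein_coding	NM_004529.4	1	14
532-5p	control	unregulated	5764.185	5526.571	0.059	0.7460	CLCN5	protein_coding	NM_000084.5	0	12
708-3p	control	unregulated	2004.533	1845.398	0.116	0.5855	TENM4	protein_coding	NM_001098816.3	3	5
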