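# Published candidate table: gene, dbSNP id, cDNA/protein change, carrier
# count, and two population MAFs are the printed values. chrom is the
# gene's chromosome; pos, ref, alt, sift and polyphen are SYNTHETIC
# placeholders (the source table prints none): positions are ascending
# order-preserving values, ref/alt are the coding-strand bases of the
# cDNA change, and scores are deterministic values inside the
# SIFT-deleterious (<0.05) and PolyPhen probably-damaging (>=0.957) bins.
chrom	pos	ref	alt	gene	dbsnp_id	cdna_change	protein_change	func_class	cases	maf_1kg	maf_1kg_eas	sift	polyphen
1	1000000	C	T	MIB2	rs376615315	c.C1153T	p.R385W	missense	2	0.0002	0.001	0.001	0.958
1	2000000	C	T	FAAH	rs77101686	c.C1067T	p.A356V	missense	2	0.008387	0.0159	0.002	0.9589
1	3000000	C	G	S100A1	rs1046256	c.C261G	p.N87K	missense	2	0.001597	0.0079	0.003	0.9598
1	4000000	T	G	RGS16	rs191231364	c.T184G	p.W62G	missense	2	0.000998	0.005	0.004	0.9607
2	5000000	G	A	MAP3K19	rs56349597	c.G3122A	p.R1041H	missense	2	0.003395	0.0169	0.005	0.9616
2	6000000	C	A	NEB	rs139636644	c.C14183A	p.A4728D	missense	2	0.011582	0.0417	0.006	0.9625
2	7000000	G	A	NEB	rs149752325	c.G14182A	p.A4728T	missense	2	0.011582	0.0417	0.007	0.9634
2	8000000	C	G	TTN	rs56137800	c.C54886G	p.P18296A	missense	2	0.004992	0.0248	0.008	0.9643
2	9000000	T	A	TNS1	rs181295117	c.T2191A	p.S731T	missense	2	0.000799	0.004	0.009	0.9652
2	10000000	C	G	TNS1	rs181839905	c.C1500G	p.I500M	missense	2	0.007987	0.0397	0.01	0.9661
3	11000000	A	G	CAND2	rs180768267	c.A1847G	p.H616R	missense	2	0.009784	0.0198	0.011	0.967
3	12000000	C	T	CCK	rs3774395	c.C283T	p.R95W	missense	2	0.002596	0.0129	0.012	0.9679
3	13000000	C	A	KALRN	rs78202770	c.C5084A	p.P1695Q	missense	2	0.013578	0.0496	0.013	0.9688
4	14000000	A	G	ATP10D	rs118048800	c.A221G	p.N74S	missense	2	0.001198	0.006	0.014	0.9697
5	15000000	G	A	SLIT3	rs2288792	c.G1184A	p.R395Q	missense	2	0.004593	0.0228	0.015	0.9706
6	16000000	T	G	ROS1	rs210968	c.T6720G	p.N2240K	missense	2	0.038139	0.0248	0.016	0.9715
6	17000000	C	T	FABP7	rs2279381	c.C182T	p.T61M	missense	4	0.006989	0.0327	0.017	0.9724
7	18000000	C	G	NUP205	rs145671518	c.C2356G	p.L786V	missense	2	0.004393	0.0208	0.018	0.9733
9	19000000	G	A	IL11RA	rs117149170	c.G782A	p.R261H	missense	3	0.004193	0.0208	0.019	0.9742
9	20000000	C	T	NPR2	rs114147262	c.C2368T	p.R790W	missense	3	0.001597	0.0069	0.02	0.9751
9	21000000	G	T	COL5A1	rs145178917	c.G378T	p.Q126H	missense	2	0.007388	0.0347	0.021	0.976
10	22000000	A	T	CUBN	rs140806389	c.A6938T	p.Y2313F	missense	2	0.009784	0.0486	0.022	0.9769
10	23000000	T	G	CUBN	rs2271460	c.T6788G	p.F2263C	missense	3	0.033746	0.0407	0.023	0.9778
10	24000000	A	G	JMJD1C	rs117647164	c.A1253G	p.K418R	missense	2	0.007388	0.0367	0.024	0.9787
10	25000000	G	A	ANXA7	rs3750575	c.G1136A	p.R379Q	missense	2	0.007788	0.0367	0.025	0.9796
10	26000000	C	T	TRIM8	rs79218728	c.C718T	p.L240F	missense	2	0.00639	0.0317	0.026	0.9805
11	27000000	G	A	LGR4	rs149204548	c.G2176A	p.A726T	missense	2	0.003195	0.0159	0.027	0.9814
11	28000000	C	T	TPCN2	rs78034812	c.C2042T	p.S681L	missense	5	0.010982	0.0387	0.028	0.9823
11	29000000	G	T	APOA5	rs2075291	c.G553T	p.G185C	missense	4	0.011382	0.0437	0.029	0.9832
12	30000000	T	C	GPR84	rs77759698	c.T1108C	p.Y370H	missense	3	0.006989	0.0347	0.03	0.9841
12	31000000	G	A	GPR84	rs11170883	c.G110A	p.G37D	missense	3	0.005791	0.0288	0.031	0.985
12	32000000	A	T	LRP1	rs79435985	c.A12161T	p.Y4054F	missense	2	0.004792	0.0238	0.032	0.9859
12	33000000	G	A	NCOR2	rs184942554	c.G3647A	p.R1216H	missense	2	0.000599	0.001	0.033	0.9868
13	34000000	C	G	AKAP11	rs2236364	c.C2162G	p.S721C	missense	2	0.003794	0.0179	0.034	0.9877
14	35000000	A	G	ESRRB	rs143477571	c.A79G	p.R27G	missense	4	0.005391	0.0268	0.035	0.9886
14	36000000	G	C	NGB	rs117207261	c.G178C	p.E60Q	missense	3	0.000799	0.004	0.036	0.9895
15	37000000	C	T	AKAP13	rs114777682	c.C568T	p.R190C	missense	2	0.001797	0.005	0.037	0.9904
16	38000000	G	T	WWOX	rs140817689	c.G129T	p.R43S	missense	2	0.001198	0.006	0.038	0.9913
17	39000000	G	A	KCNJ12	rs75029097	c.G433A	p.G145S	missense	2	0.0002	0.001	0.039	0.9922
19	40000000	C	T	ARHGEF1	rs2303797	c.C1025T	p.P342L	missense	3	0.005791	0.0268	0.04	0.9931
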