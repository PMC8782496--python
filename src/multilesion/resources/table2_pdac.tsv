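patient_id	gender	age	status	metastasis_after_surgery	os_months	dfs_months	average_tmb	average_cnv_burden	smoking	drinking	hypertension	diabetes_mellitus	location	differentiation	tnm	clinical_stage	max_diameter_cm
P1	Female	65	Dead	Yes (liver metastasis)	22	9	1.167	16.927	No	No	Yes	Yes	Head	Well/moderate	T2NXM0	IB	>3
P2	Male	64	Dead	Yes (liver metastasis)	14	7	2.219	53.723	Yes	Yes	Yes	No	Head	Moderate/poor	T3N0M0	IIA	>3
P3	Male	55	Dead	Yes (liver metastasis)	10	1	0.789	25.313	Yes	Yes	Yes	Yes	Body and tail	Moderate	T3N0M0	IIA	<=3
P4	Male	51	Dead	No	6	6	1.535	27.662	Yes	No	No	No	Body and tail	Moderate/poor	T3N1M0	IIB	>3
P5	Female	63	Live	No	32	32	1.921	10.116	No	No	No	No	Head	Well	T2N1Mx	IIB	<=3
P6	Female	64	Dead	No	11	11	1.737	5.742	No	No	No	Yes	Head	Moderate/poor	T3N1M0	IIB	>3
P7	Female	69	Live	No	32	32	3.368	5.234	No	No	Yes	Yes	Head	Moderate	T2N0M0	IB	<=3
P8	Male	44	Live	No	25	25	1.175	5.868	No	Yes	No	No	Body and tail	Moderate	T2N0M0	IB	>3
P9	Female	64	Dead	Yes (peritoneal metastasis)	12	12	1.388	3.242	No	No	Yes	No	Head	Moderate/poor	T3N1M0	IIB	>3
P10	Female	64	Live	No	25	25	0.614	5.686	No	No	Yes	No	Body and tail	Moderate	T3N0M0	IIA	<=3
P11	Female	65	Dead	Yes (liver metastasis)	16	9	0.895	11.446	Yes	No	Yes	No	Head	Moderate/poor	T3N1M0	IIB	<=3
P12	Male	64	Live	No	24	24	0.704	6.175	Yes	Yes	Yes	Yes	Head	Moderate	T3N0M0	IIA	>3
P13	Female	64	Dead	No	8	8	1.125	2.786	No	No	Yes	No	Head	Moderate	T3N1M0	IIB	>3
P14	Male	63	Dead	Yes (pulmonary metastasis)	12	6	1.020	7.993	Yes	No	Yes	Yes	Head	Well/moderate	T3N0M0	IIA	<=3
P15	Male	69	Dead	No	18	18	0.855	6.617	Yes	Yes	Yes	No	Body and tail	Moderate	T3N0M0	IIA	>3
P16	Female	73	Live	No	23	23	1.702	10.246	No	No	No	Yes	Head	Moderate	T3N1M0	IIB	<=3
P17	Male	72	Dead	No	NA	NA	1.175	5.883	No	No	Yes	Yes	Head	Moderate/poor	T3N1M0	IIB	<=3
P18	Female	64	Live	No	22	22	1.395	29.395	No	No	Yes	No	Body and tail	Moderate/poor	T3N0M0	IIA	<=3
P19	Male	42	Live	No	21	21	1.333	12.493	No	No	No	No	Body and tail	Moderate	T3N1M0	IIB	>3
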