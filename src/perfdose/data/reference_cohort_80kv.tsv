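# Reference cohort: per-case mean organ absorbed doses (mGy) and effective dose (mSv)
# for 20 dynamic CT myocardial-perfusion cases plus the reference voxel phantom,
# 80 kV / 370 mAs protocol. Transcribed published values; used as the fixture for
# cohort-statistics checks.
case	adrenals	bones	brain	breasts	colon	extrathoracic	gall_bladder	gonads	heart	kidneys	liver	lungs	lymphatic_nodes	muscle	oesophagus	oral_mucosa	pancreas	rbm	salivary_glands	skin	small_intestine	spleen	stomach	thymus	thyroid	urinary_bladder	uterus	effective_dose
1	2.91	5.39	0.05	13.27	0.10	0.43	2.62	0.01	27.36	1.33	7.22	22.99	3.88	1.20	7.89	0.56	1.40	2.94	0.50	1.17	0.38	6.08	4.98	4.57	1.77	0.00	0.01	6.25
2	2.49	5.14	0.05	15.62	0.09	0.43	2.25	0.01	26.28	1.14	7.63	20.64	3.88	0.94	13.76	0.55	1.22	2.78	0.48	1.11	0.34	6.64	3.58	3.94	1.49	0.00	0.01	6.27
3	2.20	5.55	0.03	16.03	0.07	0.28	1.92	0.01	27.10	1.00	4.84	22.95	3.88	1.29	9.68	0.36	1.03	2.92	0.31	1.00	0.28	4.48	2.88	3.29	1.17	0.00	0.01	6.27
4	2.58	6.68	0.03	22.22	0.09	0.29	2.29	0.01	37.80	1.13	7.10	25.48	3.88	1.66	13.26	0.36	1.20	3.68	0.33	1.54	0.33	6.86	4.30	2.15	1.27	0.00	0.01	7.92
5	8.56	5.68	0.03	16.71	0.19	0.29	3.53	0.01	46.59	2.67	10.51	26.18	3.88	1.89	15.73	0.35	2.44	3.38	0.32	1.41	0.52	7.80	5.35	2.57	1.43	0.01	0.01	7.73
6	2.93	5.60	0.03	25.18	0.10	0.29	2.54	0.01	38.23	1.27	8.25	25.31	3.88	1.45	12.99	0.37	1.32	3.10	0.30	1.25	0.36	10.03	5.27	2.28	1.29	0.00	0.01	8.27
7	2.51	6.98	0.04	67.20	0.08	0.35	2.09	0.01	37.47	1.09	7.09	34.14	3.88	1.93	15.37	0.45	1.10	3.76	0.39	2.06	0.30	6.08	5.21	3.84	1.45	0.00	0.01	14.56
8	2.99	7.18	0.04	22.15	0.09	0.30	2.60	0.01	39.42	1.27	8.20	31.97	3.88	1.83	16.31	0.39	1.35	3.87	0.34	1.50	0.36	6.19	4.45	3.16	1.24	0.00	0.01	8.91
9	2.34	6.14	0.03	14.80	0.08	0.31	2.06	0.01	32.44	1.04	5.98	24.54	3.88	1.33	13.39	0.40	1.09	3.28	0.33	1.12	0.29	4.61	3.04	3.76	1.28	0.00	0.01	6.60
10	3.84	7.65	0.04	13.25	0.12	0.35	3.42	0.01	46.49	1.61	11.77	33.54	3.88	2.76	17.77	0.45	1.75	4.26	0.40	1.71	0.46	10.32	7.38	3.14	1.36	0.01	0.01	8.75
11	2.62	5.17	0.05	27.60	0.10	0.44	2.38	0.01	25.48	1.21	6.39	22.18	3.88	1.69	10.08	0.58	1.28	2.75	0.51	1.21	0.35	5.36	3.60	4.37	1.60	0.00	0.01	7.77
12	2.52	5.56	0.05	27.27	0.09	0.41	2.23	0.01	31.16	1.16	6.50	22.86	3.88	1.48	9.83	0.53	1.24	3.03	0.45	1.15	0.34	5.56	4.31	4.13	1.47	0.00	0.01	7.93
13	3.12	4.21	0.04	36.98	0.15	0.36	2.86	0.01	18.26	1.55	7.62	15.80	3.88	0.85	7.19	0.47	1.65	2.35	0.38	0.99	0.47	6.96	3.46	2.63	1.08	0.01	0.01	7.88
14	4.24	5.14	0.03	27.75	0.17	0.26	3.89	0.01	31.00	1.92	9.74	20.63	3.88	1.41	12.69	0.34	2.08	2.85	0.29	1.31	0.57	12.02	5.21	2.63	1.03	0.01	0.01	8.03
15	2.73	5.61	0.04	15.39	0.11	0.36	2.53	0.01	31.58	1.24	6.78	24.22	3.88	1.41	12.42	0.46	1.37	2.98	0.41	1.25	0.37	5.46	3.71	2.82	1.29	0.01	0.01	6.71
16	2.83	4.90	0.04	10.49	0.12	0.34	2.62	0.01	23.60	1.37	7.53	17.29	3.88	1.15	6.58	0.45	1.48	2.69	0.38	0.99	0.41	6.62	3.55	2.45	1.07	0.01	0.01	4.95
17	2.30	4.95	0.07	18.54	0.09	0.54	2.07	0.01	29.42	1.08	6.43	21.35	3.88	1.23	9.15	0.70	1.12	2.66	0.62	1.07	0.31	5.35	4.64	5.07	1.88	0.00	0.01	6.61
18	3.45	6.66	0.04	27.70	0.13	0.33	3.06	0.01	32.07	1.55	8.19	24.88	3.88	1.21	9.43	0.43	1.66	3.66	0.38	1.21	0.45	6.84	5.56	2.16	1.14	0.01	0.01	8.46
19	2.62	5.72	0.03	10.13	0.09	0.31	2.34	0.01	36.18	1.17	6.83	23.27	3.88	1.58	11.82	0.40	1.24	3.06	0.36	1.12	0.34	5.05	3.41	3.23	1.22	0.00	0.01	5.91
20	2.84	3.92	0.04	5.12	0.12	0.39	2.58	0.01	23.14	1.35	6.57	18.61	3.88	0.92	9.22	0.49	1.46	2.19	0.41	0.88	0.41	6.03	3.46	2.89	1.60	0.01	0.01	4.44
ICRP	3.61	5.35	0.03	46.81	0.13	0.27	3.38	0.01	30.28	1.61	11.59	25.79	3.88	1.97	11.13	0.35	1.69	3.19	0.29	3.00	0.45	7.62	5.89	2.94	0.97	0.00	0.00	11.13
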