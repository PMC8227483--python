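# Reference cohort: per-case mean organ absorbed doses (mGy) and effective dose (mSv)
# for 20 dynamic CT myocardial-perfusion cases plus the reference voxel phantom,
# 100 kV / 300 mAs protocol. Transcribed published values; used as the fixture for
# cohort-statistics checks.
case	adrenals	bones	brain	breasts	colon	extrathoracic	gall_bladder	gonads	heart	kidneys	liver	lungs	lymphatic_nodes	muscle	oesophagus	oral_mucosa	pancreas	rbm	salivary_glands	skin	small_intestine	spleen	stomach	thymus	thyroid	urinary_bladder	uterus	effective_dose
1	5.83	10.08	0.13	22.82	0.25	0.89	5.25	0.02	47.90	2.72	13.18	39.94	6.91	2.15	14.29	1.12	2.87	6.00	1.00	2.06	0.80	11.23	9.18	8.42	3.47	0.01	0.02	11.09
2	5.00	9.77	0.13	26.77	0.22	0.86	4.54	0.02	46.43	2.36	13.95	36.10	6.91	1.70	24.70	1.10	2.52	5.78	0.98	1.93	0.71	12.27	6.80	7.36	2.95	0.01	0.02	11.16
3	4.35	10.32	0.08	27.52	0.18	0.58	3.82	0.02	47.22	2.06	8.88	39.53	6.91	2.29	16.93	0.73	2.12	5.94	0.63	1.79	0.60	8.29	5.41	6.14	2.31	0.01	0.01	11.03
4	5.07	11.91	0.09	37.98	0.21	0.59	4.49	0.02	64.79	2.28	12.75	43.48	6.91	2.88	23.27	0.73	2.44	7.17	0.66	2.66	0.69	12.55	7.92	3.99	2.42	0.01	0.02	13.79
5	16.20	9.32	0.08	28.61	0.42	0.59	6.79	0.03	79.50	5.24	18.67	44.84	6.91	3.31	27.38	0.70	4.76	6.04	0.65	2.44	1.05	14.10	9.84	4.68	2.73	0.02	0.03	13.43
6	5.78	9.79	0.08	43.29	0.23	0.59	5.03	0.02	65.80	2.58	14.94	43.62	6.91	2.56	22.69	0.75	2.70	5.91	0.62	2.19	0.74	18.60	9.61	4.26	2.49	0.01	0.02	14.44
7	4.87	11.37	0.11	112.76	0.18	0.70	4.07	0.02	63.76	2.17	12.95	57.65	6.91	3.36	26.21	0.88	2.22	6.67	0.76	3.50	0.62	10.92	9.29	6.97	2.77	0.01	0.02	24.68
8	5.75	13.16	0.09	37.62	0.22	0.61	5.07	0.02	67.24	2.53	14.57	53.74	6.91	3.16	27.71	0.78	2.70	7.75	0.69	2.62	0.74	11.06	8.03	5.81	2.37	0.01	0.02	15.33
9	4.64	11.07	0.09	25.56	0.19	0.65	4.13	0.02	56.24	2.14	10.93	42.23	6.91	2.35	23.44	0.82	2.25	6.46	0.69	1.99	0.62	8.50	5.69	6.93	2.52	0.01	0.02	11.60
10	7.34	12.95	0.10	22.59	0.28	0.69	6.57	0.02	78.83	3.16	20.70	56.36	6.91	4.73	30.29	0.90	3.45	7.87	0.78	2.94	0.93	18.06	13.11	5.77	2.61	0.01	0.02	15.00
11	5.26	9.55	0.13	47.18	0.23	0.90	4.79	0.02	45.08	2.50	11.74	38.79	6.91	3.02	18.09	1.15	2.64	5.56	1.02	2.11	0.74	9.97	6.78	8.19	3.20	0.01	0.02	13.69
12	5.03	10.27	0.12	46.70	0.22	0.83	4.49	0.02	54.67	2.38	12.00	39.83	6.91	2.64	17.60	1.07	2.56	6.11	0.90	2.03	0.72	10.30	8.05	7.70	2.91	0.01	0.02	13.96
13	6.24	8.11	0.11	63.02	0.34	0.72	5.75	0.02	32.86	3.18	14.17	27.99	6.91	1.56	13.27	0.96	3.39	4.95	0.79	1.75	0.98	12.87	6.63	5.13	2.21	0.02	0.02	13.90
14	8.29	9.62	0.08	47.50	0.37	0.56	7.58	0.03	54.15	3.88	17.67	35.98	6.91	2.52	22.56	0.70	4.19	5.82	0.60	2.30	1.17	21.65	9.66	5.00	2.08	0.02	0.03	14.16
15	5.41	10.46	0.10	26.54	0.26	0.74	5.04	0.02	55.27	2.53	12.43	41.72	6.91	2.50	21.70	0.95	2.81	6.06	0.83	2.20	0.78	10.00	6.93	5.34	2.52	0.01	0.02	11.81
16	5.69	9.68	0.10	18.09	0.27	0.70	5.22	0.02	41.77	2.81	13.85	30.33	6.91	2.07	12.12	0.91	3.04	5.81	0.78	1.76	0.86	12.18	6.73	4.75	2.18	0.01	0.02	8.92
17	4.68	9.51	0.16	31.98	0.22	1.11	4.20	0.02	51.96	2.25	11.81	37.55	6.91	2.23	16.73	1.41	2.36	5.60	1.23	1.89	0.67	10.05	8.67	9.49	3.74	0.01	0.02	11.82
18	6.71	12.57	0.10	47.19	0.29	0.67	6.03	0.02	55.71	3.11	14.84	42.67	6.91	2.14	16.85	0.86	3.35	7.55	0.77	2.13	0.93	12.31	10.07	4.13	2.25	0.02	0.02	14.79
19	5.16	10.22	0.09	17.54	0.21	0.64	4.69	0.02	62.42	2.38	12.41	40.07	6.91	2.80	20.48	0.82	2.55	5.97	0.73	1.98	0.70	9.28	6.33	6.00	2.42	0.01	0.02	10.40
20	5.68	7.59	0.11	9.21	0.27	0.80	5.24	0.02	41.48	2.79	12.23	32.48	6.91	1.66	16.52	1.00	3.03	4.64	0.85	1.55	0.86	11.10	6.60	5.45	3.15	0.01	0.02	8.04
ICRP	7.05	8.97	0.08	78.47	0.28	0.54	6.53	0.01	51.99	3.20	20.62	44.49	6.91	3.46	20.10	0.70	3.37	5.82	0.58	5.06	0.91	13.76	10.65	5.48	1.92	0.01	0.01	19.11
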