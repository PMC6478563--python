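family_id	fsir	fsir_p	n_obs	n_exp	n_cases_dna	n_meioses	thr_significant	thr_suggestive
709	2.69	<0.0001	27	10.04	8	35	6.36E-08	6.41E-07
1881	3.12	<0.0001	21	9.31	4	17	2.03E-06	3.00E-05
2082	3.99	<0.0001	19	4.77	3	15	3.93E-06	9.78E-05
7785	2.78	<0.0001	28	10.08	6	26	1.45E-07	1.82E-06
8556	2.85	<0.0001	41	14.39	7	37	8.99E-08	1.01E-06
11593	2.31	0.0002	25	10.82	6	29	1.28E-07	1.70E-06
12291	2.43	0.0001	23	9.48	6	29	1.59E-07	1.96E-06
27251	2.43	0.0001	36	16.93	12	52	1.16E-09	1.41E-08
36667	3.61	0.0039	7	1.61	4	17	7.99E-07	1.56E-05
37661	2.06	0.0031	19	9.21	5	20	1.79E-06	1.91E-05
40780	3.61	0.0038	7	1.94	4	19	1.59E-06	2.57E-05
41469	2.29	0.0013	18	7.86	4	20	4.24E-06	5.86E-05
43035	2.46	<0.0001	36	14.63	7	31	1.09E-07	1.15E-06
43580	2.45	0.0004	19	7.75	6	29	2.93E-07	3.08E-06
46547	2.48	<0.0001	29	11.71	6	28	2.75E-07	2.92E-06
60205	2.26	0.0007	21	9.31	5	26	5.07E-07	6.52E-06
66494	2.45	0.0001	24	9.87	7	34	5.45E-08	6.47E-07
68939	2.21	0.0007	22	9.97	8	41	3.66E-08	3.95E-07
91500	3.19	0.0003	13	4.07	4	16	1.24E-06	2.18E-05
129334	2.75	<0.0001	25	9.09	7	36	6.92E-08	8.32E-07
148039	3.65	0.0002	12	3.29	4	15	5.14E-06	5.73E-05
176860	2.71	<0.0001	43	15.88	9	39	3.28E-08	3.08E-07
185855	2.96	0.0003	15	5.06	6	25	2.46E-07	2.24E-06
209487	2.82	<0.0001	26	9.23	7	32	1.19E-07	1.25E-06
233769	2.5	<0.0001	33	13.19	11	50	1.58E-08	1.40E-07
265545	4.05	0.001	8	1.98	5	17	2.74E-06	3.82E-05
540295	2.59	<0.0001	43	16.59	5	31	1.73E-07	3.10E-06
540775	2.46	0.003	13	5.28	7	34	5.88E-08	7.45E-07
544252	3.21	0.0025	9	2.8	4	19	7.48E-07	1.43E-05
553615	2.04	<0.0001	81	39.71	13	69	2.69E-10	3.74E-09
554151	2.38	0.003	14	5.89	7	32	9.98E-08	1.05E-06
587072	2.39	0.003	14	5.86	5	25	1.39E-06	1.55E-05
590241	2.47	0.0004	19	7.7	8	38	2.86E-08	3.16E-07
595955	2.48	<0.0001	39	15.73	7	39	5.35E-08	6.62E-07
601627	2.86	<0.0001	69	24.14	12	70	7.06E-10	9.14E-09
603481	2.64	0.0003	18	6.83	9	37	5.09E-08	5.35E-07
622459	2.54	0.0001	22	8.68	4	18	1.75E-06	2.60E-05
755858	2.28	0.001	19	8.33	5	24	3.77E-07	5.48E-06
756794	2.7	0.0002	18	6.68	5	24	3.94E-07	5.67E-06
791533	3.67	0.001	9	2.45	3	17	3.09E-06	8.38E-05
807334	2.5	0.0001	24	9.58	6	30	3.25E-07	3.57E-06
923763	4.41	<0.0001	14	3.18	3	15	3.33E-06	8.86E-05
957634	3.7	0.0001	12	3.24	3	15	3.22E-06	8.40E-05
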