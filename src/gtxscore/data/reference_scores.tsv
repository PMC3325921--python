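probe_id	specificity	specificity_score	ave_ratio	ave_ratio_score	positive_condition	positive_condition_score	positive_chemical	positive_chemical_score	p_value	p_value_score	basal	basal_score	reverse_change	reverse_change_score	cv_percent	cv_percent_score	total_score	symbol
1426936_at	1.00	5	10.62	5	11.5	5	6	5	0.14	5	0.92	0	0.0	2	64	2	32.0	BC005512
1417185_at	1.00	5	3.98	2	14.5	5	6	5	0.07	5	2.35	3	0.0	2	27	4	31.5	Ly6a
1433691_at	1.00	5	3.31	2	5.0	2	5	4	0.21	4	2.64	4	2.0	5	24	4	28.5	Ppp1r3c
1449002_at	1.00	5	4.40	2	12.0	5	6	5	0.33	2	1.80	1	0.0	2	26	4	27.5	Phlda3
1421040_a_at	1.00	5	2.49	2	5.5	2	5	4	0.18	4	2.63	4	0.0	2	33	4	27.0	Gsta2
1424638_at	0.83	3	24.58	5	15.0	5	7	5	0.19	4	1.51	0	0.0	2	70	2	27.0	Cdkn1a
1450016_at	1.00	5	3.26	2	11.0	5	5	4	0.35	1	2.13	2	0.0	2	12	5	26.5	Ccng
1450017_at	1.00	5	4.55	2	11.0	5	5	4	0.29	2	1.79	1	0.0	2	23	4	26.5	Ccng
1420827_a_at	0.92	4	7.88	4	11.0	5	5	4	0.33	2	1.75	1	0.0	2	43	3	26.0	Ccng
1416578_at	1.00	5	2.88	2	5.0	2	5	4	0.17	4	1.92	1	0.0	2	35	4	25.5	Rbx1
1424744_at	1.00	5	2.42	0	6.5	3	6	5	0.46	0	3.01	5	2.0	5	33	4	25.0	Sds
1425631_at	1.00	5	3.72	2	4.0	1	4	2	0.15	5	2.09	2	4.0	5	38	3	25.0	Ppp1r3c
1416125_at	1.00	5	2.49	2	5.0	2	4	2	0.12	5	2.28	3	0.0	2	71	2	24.5	Fkbp5
1419874_x_at	0.90	4	5.77	3	9.0	4	5	4	0.15	5	1.37	0	-1.0	1	107	0	24.5	AI467657
1427422_at	0.83	3	3.15	2	10.0	5	6	5	0.27	3	1.99	1	1.0	3	46	3	24.5	BM122014
1442026_at	0.83	3	3.70	2	10.0	5	5	4	0.11	5	1.62	0	0.0	2	50	3	24.5	AI467657
1416926_at	0.86	3	3.37	2	12.0	5	6	5	0.31	2	2.25	2	0.0	2	24	4	24.0	Stinp
1448265_x_at	1.00	5	2.55	2	7.5	3	6	5	0.36	1	2.02	2	-1.0	1	52	3	24.0	Eva
1455892_x_at	0.91	4	2.52	2	10.5	5	5	4	0.48	0	2.92	5	1.0	3	80	2	24.0	BB794742
1418787_at	1.00	5	1.89	0	5.0	2	5	4	0.31	2	3.16	5	0.0	2	13	4	23.5	Mbl2
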