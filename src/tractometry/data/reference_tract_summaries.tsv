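abbreviation	comparison	fa_percent_tract	fa_r	md_percent_tract	md_r	rd_percent_tract	rd_r	ax_percent_tract	ax_r
L-ATR	bvFTD_vs_control	59.2	0.41	89.2	0.55	85.6	0.54	76.0	0.49
R-ATR	bvFTD_vs_control	62.2	0.41	87.7	0.53	85.9	0.52	73.4	0.47
CC-FNR	bvFTD_vs_control	93.4	0.60	97.7	0.61	98.3	0.64	56.7	0.40
CC-OCC	bvFTD_vs_control	17.7	0.48	34.7	0.51	36.4	0.53	7.0	0.34
CC-PAR	bvFTD_vs_control	37.6	0.49	59.9	0.52	64.4	0.55	15.4	0.35
CC-POCG	bvFTD_vs_control	61.7	0.50	67.0	0.53	75.8	0.55	17.5	0.35
CC-PRCG	bvFTD_vs_control	59.0	0.50	68.2	0.52	77.2	0.55	15.9	0.34
CC-TEM	bvFTD_vs_control	25.6	0.49	53.7	0.52	50.0	0.54	34.8	0.36
L-CGC	bvFTD_vs_control	56.3	0.51	74.0	0.53	79.9	0.56	24.1	0.35
R-CGC	bvFTD_vs_control	57.4	0.51	79.0	0.54	82.0	0.57	26.2	0.35
L-CST	bvFTD_vs_control	2.7	0.51	40.2	0.52	13.3	0.54	40.0	0.37
R-CST	bvFTD_vs_control	4.2	0.51	51.0	0.52	22.4	0.54	46.4	0.39
L-IFO	bvFTD_vs_control	49.9	0.52	70.8	0.55	66.5	0.57	41.4	0.37
R-IFO	bvFTD_vs_control	38.8	0.51	63.7	0.54	59.0	0.56	34.8	0.36
L-ILF	bvFTD_vs_control	14.2	0.47	53.7	0.52	44.3	0.53	34.8	0.37
R-ILF	bvFTD_vs_control	18.9	0.47	49.1	0.50	45.4	0.52	17.5	0.34
L-PHC	bvFTD_vs_control	27.6	0.48	69.4	0.51	62.6	0.53	43.2	0.35
R-PHC	bvFTD_vs_control	23.4	0.47	67.6	0.51	59.8	0.53	33.2	0.35
L-SLF	bvFTD_vs_control	41.3	0.48	83.0	0.53	75.0	0.54	29.9	0.35
L-UNC	bvFTD_vs_control	94.6	0.53	97.9	0.56	99.5	0.58	70.4	0.38
R-UNC	bvFTD_vs_control	81.3	0.52	97.8	0.56	98.7	0.58	61.6	0.38
L-ATR	EOAD_vs_control	1.3	0.15	16.1	0.24	13.4	0.21	9.5	0.23
R-ATR	EOAD_vs_control	0.0	0.12	11.2	0.20	5.6	0.18	6.1	0.21
CC-FNR	EOAD_vs_control	3.4	0.20	32.7	0.29	27.9	0.27	14.1	0.23
CC-OCC	EOAD_vs_control	0.7	0.18	8.6	0.25	5.0	0.24	9.0	0.23
CC-PAR	EOAD_vs_control	10.6	0.21	43.1	0.30	43.1	0.28	24.4	0.26
CC-POCG	EOAD_vs_control	9.5	0.22	23.2	0.28	32.0	0.28	9.8	0.24
CC-PRCG	EOAD_vs_control	7.5	0.22	19.9	0.28	27.8	0.27	9.0	0.24
CC-TEM	EOAD_vs_control	0.3	0.19	35.0	0.29	14.1	0.26	40.5	0.27
L-CGC	EOAD_vs_control	6.5	0.21	31.1	0.28	30.9	0.28	6.7	0.23
R-CGC	EOAD_vs_control	1.8	0.20	25.3	0.28	24.7	0.27	4.3	0.22
L-CST	EOAD_vs_control	1.2	0.19	4.4	0.26	4.5	0.25	8.2	0.22
R-CST	EOAD_vs_control	1.0	0.19	5.5	0.25	5.7	0.24	3.9	0.22
L-IFO	EOAD_vs_control	1.3	0.19	12.3	0.25	12.3	0.25	2.9	0.21
R-IFO	EOAD_vs_control	0.6	0.19	7.1	0.25	7.4	0.24	1.2	0.20
L-ILF	EOAD_vs_control	0.7	0.18	24.2	0.27	16.6	0.25	11.5	0.23
R-ILF	EOAD_vs_control	0.2	0.17	17.2	0.26	6.9	0.23	11.3	0.23
L-PHC	EOAD_vs_control	14.1	0.19	33.1	0.27	39.1	0.25	9.4	0.23
R-PHC	EOAD_vs_control	9.9	0.19	30.4	0.27	35.7	0.26	9.9	0.23
L-SLF	EOAD_vs_control	2.3	0.18	34.5	0.28	17.0	0.25	16.1	0.24
L-UNC	EOAD_vs_control	4.2	0.20	15.0	0.27	20.8	0.25	5.7	0.23
R-UNC	EOAD_vs_control	1.5	0.19	8.8	0.27	8.2	0.25	5.2	0.23
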