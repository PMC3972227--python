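allele	Han	Manchu	Mongol	Hui	Korean	Xibe
A*01	4.686	5.501	6.746	1.980	3.906	3.226
A*02	32.883	33.274	31.349	33.663	34.375	27.419
A*03	4.630	3.801	5.159	5.941	1.563	3.226
A*11	15.935	15.206	13.095	10.891	14.063	19.355
A*23	0.330	0.134	0.397			1.613
A*24	16.015	17.039	15.079	17.327	19.531	8.065
A*25	0.042
A*26	3.220	3.309	4.365	4.951	4.688
A*29	0.904	0.581		0.990	0.781	1.613
A*30	7.166	7.021	5.556	6.931	4.688	14.516
A*31	4.173	4.875	7.143	5.941	4.688	4.839
A*32	1.573	1.521	1.984	2.475	0.781	4.839
A*33	7.286	6.574	7.143	7.921	10.156	8.065
A*34	0.017
A*66	0.090	0.045
A*68	0.955	0.984	1.587	0.990		3.226
A*69	0.078	0.134	0.397		0.781
A*74	0.015
Unknown	0.002
B*07	3.494	2.996	2.778	1.980	3.906	3.226
B*08	0.909	0.626	0.794	0.495	0.781	1.613
B*13	12.167	12.567	12.698	12.871	6.250	17.742
B*14	0.002
B*14(64)	0.081	0.045	0.794		0.781
B*14(65)	0.330	0.268		2.475
B*15	0.464	0.537		0.495
B*15(62)	7.239	7.737	4.365	9.406	8.594	6.452
B*15(63)	0.303	0.179	0.794	0.990		1.613
B*15(70)	0.032	0.045
B*15(71)	1.928	2.504	2.381	1.980	1.563	3.226
B*15(72)	0.137	0.134	0.397
B*15(75)	4.342	4.025	1.984	4.951	3.125	6.452
B*15(76)	0.068	0.045
B*15(77)	0.083	0.089
B*18	0.540	0.447	0.794	2.475	0.781
B*27	1.740	1.610	0.397	0.990	1.563	1.613
B*35	5.487	5.456	8.730	7.426	7.813	4.839
B*37	1.610	1.699	3.968	1.485	0.781	4.839
B*38	2.311	2.102	1.984	6.931	1.563
B*39	1.906	1.878	2.778	2.475	3.125
B*40	0.489	0.626	1.190		0.781
B*40(40)	0.015	0.045
B*40(60)	6.355	7.156	5.952	3.960	4.688	6.452
B*40(61)	7.515	7.290	8.730	4.951	9.375	3.226
B*41	0.173	0.045		0.990
B*42	0.034	0.045
B*44	5.089	4.070	4.762	2.475	4.688	6.452
B*45	0.132	0.045
B*46	6.966	7.111	6.746	6.436	4.688	8.065
B*47	0.034
B*48	3.819	3.444	1.984	2.970	5.469	4.839
B*49	0.188	0.089	0.794	0.495
B*50	0.902	0.939	1.190	1.980	0.781	3.226
B*51	7.017	7.111	4.762	7.426	4.688	6.452
B*52	3.655	3.220	3.175	4.951	3.906	4.839
B*53	0.042	0.045
B*54	3.132	3.846	2.778	0.990	4.688
B*55	1.710	1.744	3.571		2.344
B*55(54)	0.024
B*56	0.279	0.268
B*57	1.654	2.191	4.365	0.990	1.563
B*58	4.298	4.562	2.778	3.465	6.250	4.839
B*59	0.098	0.089			3.125
B*67	1.033	1.208	1.190	0.495	2.344
B*73	0.027
B*78	0.002
B*81	0.147	0.045	0.397
DRB1*01	2.71	1.97	4.37	6.44	2.34	4.84
DRB1*03	0.03	0.09	0.40
DRB1*03(17)	3.59	4.03	2.78	4.46	3.13	4.84
DRB1*04	10.27	11.36	10.71	15.35	17.97	6.45
DRB1*07	11.66	12.48	13.49	11.88	7.81	25.81
DRB1*08	6.05	6.57	4.76	5.45	7.81	3.23
DRB1*09	13.56	13.28	11.90	10.40	11.72	11.29
DRB1*10	1.60	1.43	3.57	0.99	0.78	3.23
DRB1*11	6.64	5.50	6.35	6.44	7.03	8.06
DRB1*12	12.00	12.84	11.90	12.87	6.25	4.84
DRB1*13	6.31	5.23	4.76	3.96	7.81	4.84
DRB1*14	6.64	6.31	7.14	4.46	9.38	12.90
DRB1*15	17.37	17.31	15.87	15.84	17.97	9.68
DRB1*16	1.56	1.61	1.98	1.49
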