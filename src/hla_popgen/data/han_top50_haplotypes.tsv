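A	B	DRB1	frequency	ld_percent
A*30	B*13	DRB1*07	0.0488	4.7783
A*02	B*46	DRB1*09	0.0238	2.0694
A*02	B*13	DRB1*12	0.0161	1.1299
A*33	B*58	DRB1*03(17)	0.0131	1.2988
A*33	B*58	DRB1*13	0.0116	1.1402
A*02	B*46	DRB1*08	0.0115	1.0114
A*33	B*44	DRB1*13	0.0114	1.1166
A*02	B*40(61)	DRB1*09	0.0091	0.5749
A*01	B*57	DRB1*07	0.0080	0.7910
A*01	B*37	DRB1*10	0.0079	0.7888
A*02	B*15(75)	DRB1*09	0.0079	0.5964
A*02	B*15(62)	DRB1*15	0.0078	0.3665
A*11	B*15(62)	DRB1*04	0.0073	0.6115
A*11	B*15(75)	DRB1*12	0.0068	0.5970
A*24	B*40(61)	DRB1*09	0.0066	0.4968
A*33	B*44	DRB1*07	0.0065	0.6068
A*24	B*54	DRB1*04	0.0064	0.5885
A*11	B*13	DRB1*12	0.0058	0.3473
A*02	B*40(61)	DRB1*15	0.0055	0.1208
A*03	B*07	DRB1*15	0.0055	0.5219
A*11	B*52	DRB1*15	0.0053	0.4288
A*02	B*40(60)	DRB1*15	0.0052	0.1570
A*24	B*40(61)	DRB1*15	0.0051	0.3009
A*02	B*40(61)	DRB1*12	0.0051	0.2135
A*02	B*51	DRB1*09	0.0051	0.1971
A*02	B*15(75)	DRB1*15	0.0049	0.2420
A*24	B*15(62)	DRB1*04	0.0048	0.3609
A*11	B*13	DRB1*15	0.0046	0.3069
A*32	B*52	DRB1*15	0.0046	0.4598
A*02	B*15(75)	DRB1*12	0.0046	0.2887
A*02	B*48	DRB1*09	0.0044	0.2443
A*03	B*44	DRB1*13	0.0043	0.4151
A*24	B*13	DRB1*12	0.0042	0.1862
A*24	B*35	DRB1*15	0.0041	0.2574
A*02	B*35	DRB1*15	0.0041	0.0966
A*11	B*40(60)	DRB1*12	0.0040	0.2785
A*24	B*15(62)	DRB1*15	0.0040	0.1986
A*02	B*15(62)	DRB1*04	0.0040	0.1555
A*02	B*15(62)	DRB1*12	0.0039	0.1044
A*02	B*48	DRB1*15	0.0039	0.1719
A*02	B*13	DRB1*07	0.0038	-0.0865
A*11	B*40(60)	DRB1*09	0.0038	0.2427
A*02	B*51	DRB1*14	0.0037	0.2168
A*11	B*51	DRB1*09	0.0036	0.2084
A*02	B*15(71)	DRB1*04	0.0036	0.2949
A*24	B*46	DRB1*09	0.0035	0.1987
A*11	B*40(60)	DRB1*15	0.0035	0.1741
A*24	B*40(61)	DRB1*12	0.0034	0.1956
A*02	B*50	DRB1*07	0.0034	0.3054
A*02	B*46	DRB1*12	0.0034	0.0651
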