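linkage_group	level	n_markers	genetic_cm	printed_density	printed_max_gap_cm	printed_gap_lt5_pct	physical_mb	printed_rate_per_mb
A01	chrom	396	186.37	2.12	7.98	99.49	105.79	3.74
A02	chrom	179	146.82	1.22	5.05	99.44	91.89	1.95
A03	chrom	190	154.51	1.23	10.89	98.41	134.06	1.42
A04	chrom	180	141.79	1.27	5.36	98.88	122.25	1.47
A05	chrom	270	150.28	1.80	4.61	100.00	109.35	2.47
A06	chrom	505	161.58	3.13	8.65	98.21	110.91	4.55
A07	chrom	152	161.61	0.94	9.45	98.68	75.43	2.02
A08	chrom	77	159.90	0.48	11.95	92.11	48.00	1.60
A09	chrom	214	123.29	1.74	5.14	99.53	119.85	1.79
A10	chrom	220	147.32	1.49	5.08	99.54	109.09	2.02
B01	chrom	172	134.71	1.28	5.09	99.42	136.80	1.26
B02	chrom	174	149.98	1.16	6.46	97.69	105.81	1.64
B03	chrom	279	143.03	1.95	5.17	98.92	134.88	2.07
B04	chrom	694	119.66	5.80	16.84	99.71	129.59	5.36
B05	chrom	171	127.54	1.34	3.74	100.00	147.65	1.16
B06	chrom	215	126.04	1.71	4.82	100.00	136.43	1.58
B07	chrom	178	154.25	1.15	11.73	98.87	125.76	1.42
B08	chrom	185	149.64	1.24	7.44	98.91	128.40	1.44
B09	chrom	199	129.82	1.53	7.21	98.48	145.44	1.37
B10	chrom	187	147.32	1.27	8.88	99.46	135.29	1.38
A_subgenome	subgenome	2383	1533.47	1.55	11.95	98.43	1026.62	2.32
B_subgenome	subgenome	2454	1381.99	1.78	16.84	99.15	1326.02	1.85
Total	genome	4837	2915.46	1.66	16.84	98.79	2352.64	2.06
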