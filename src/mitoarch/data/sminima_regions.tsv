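# Per-region nucleotide composition of the Siliqua minima mitogenome as
# published: size (bp), base percentages, A+T%, and the published strand
# skews (AT-skew = (A-T)/(A+T), GC-skew = (G-C)/(G+C), 3 dp).
# Note: the published cox2 size (948 bp) disagrees with the annotation
# coordinates (12,598..13,282 = 685 bp); both are retained as printed.
region	size_bp	A_pct	T_pct	G_pct	C_pct	AT_pct	at_skew	gc_skew
mitogenome	17064	25.41	41.00	22.93	10.62	66.41	-0.235	0.367
cox1	1569	20.59	44.04	22.56	12.81	64.63	-0.363	0.276
nad1	939	18.74	46.01	25.45	9.80	64.75	-0.421	0.444
nad5	1698	21.85	46.11	22.08	9.95	67.96	-0.357	0.379
cytb	1146	21.90	44.68	20.94	12.48	66.58	-0.342	0.253
nad6	501	26.75	45.11	21.36	6.79	71.86	-0.255	0.518
atp6	699	22.46	46.64	19.46	11.44	69.10	-0.350	0.260
cox3	789	21.93	42.71	22.31	13.05	64.64	-0.321	0.262
nad2	1017	22.91	44.05	22.91	10.13	66.96	-0.316	0.387
cox2	948	27.11	34.81	27.85	10.23	61.92	-0.124	0.463
nad4l	288	21.53	44.10	27.78	6.60	65.63	-0.344	0.616
nad4	1314	21.31	46.35	23.67	8.68	67.66	-0.370	0.463
nad3	354	17.80	48.31	26.55	7.34	66.11	-0.462	0.567
CR	1371	32.31	27.79	29.76	10.14	60.10	0.075	0.492
tRNAs	1452	30.51	35.61	21.28	12.60	66.12	-0.077	0.256
rRNAs	2076	34.97	33.86	18.98	12.19	68.83	0.016	0.218
PCGs	11262	22.02	44.33	23.17	10.49	66.35	-0.336	0.377
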