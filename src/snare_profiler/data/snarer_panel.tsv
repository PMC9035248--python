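# SNARER descriptor panel: 24 per-residue physicochemical scales
# (17 AAindex accessions + the 7 Fauchere et al. amino-acid parameter sets).
# Values transcribed from the public AAindex flat-file release and the
# Fauchere et al. parameter table; the code column records the source
# accession so every row is auditable against the original release.
# Columns after the first three hold the residue values in fixed
# lexicographic alphabet order.
code	source	description	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
ARGP820102	AAindex	Signal sequence helical potential	1.18	1.89	0.05	0.11	1.96	0.49	0.31	1.45	0.06	3.23	2.67	0.23	0.76	0.72	0.20	0.97	0.84	1.08	0.77	0.39
CHAM830101	AAindex	The Chou-Fasman parameter of the coil conformation	0.71	1.19	1.21	0.84	0.71	1.52	1.07	0.66	0.99	0.69	0.59	1.37	1.61	0.87	1.06	1.34	1.08	0.63	0.76	1.07
CHAM830107	AAindex	A parameter of charge transfer capability	0	0	1	1	0	0	0	0	0	0	0	1	0	1	0	0	0	0	0	0
CHAM830108	AAindex	A parameter of charge transfer donor capability	0	1	0	0	0	0	1	0	0	0	1	0	0	0	0	0	0	0	1	1
CHOP780204	AAindex	Normalized frequency of N-terminal helix	1.32	0.79	1.41	1.44	1.01	0.53	1.09	0.92	0.77	1.08	1.11	0.88	1.00	1.22	0.81	0.85	0.80	0.92	1.08	0.68
CHOP780205	AAindex	Normalized frequency of C-terminal helix	1.21	0.92	0.76	1.01	1.10	0.67	1.18	0.98	1.27	1.26	1.29	0.94	0.43	1.12	1.05	0.88	0.82	0.93	1.07	1.03
CHOP780206	AAindex	Normalized frequency of N-terminal non helical region	0.70	0.65	0.98	0.77	0.93	1.41	1.22	0.78	1.15	0.85	0.81	1.42	1.10	0.75	0.74	1.42	1.21	0.75	0.62	1.10
CHOP780207	AAindex	Normalized frequency of C-terminal non helical region	0.74	1.06	1.17	0.87	0.66	1.26	1.06	0.74	1.04	0.69	0.81	1.13	1.46	0.87	1.04	1.12	0.95	0.66	0.99	0.87
EISD860101	AAindex	Solvation free energy	0.67	0.38	-1.20	-0.76	2.30	0.00	0.64	1.90	-0.57	1.90	2.40	-0.60	1.20	-0.22	-2.10	0.01	0.52	1.50	2.60	1.60
FAUJ880108	AAindex	Localized electrical effect	-0.01	0.12	0.15	0.07	0.03	0.00	0.08	-0.01	0.00	-0.01	0.04	0.06	0.00	0.05	0.04	0.11	0.04	0.01	0.00	0.03
FAUJ880111	AAindex	Positive charge	0	0	0	0	0	0	0.5	0	1	0	0	0	0	0	1	0	0	0	0	0
FAUJ880112	AAindex	Negative charge	0	0	1	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
GUYH850101	AAindex	Partition energy	0.10	-1.42	0.78	0.83	-2.12	0.33	-0.50	-1.13	1.40	-1.18	-1.59	0.48	0.73	0.95	1.91	0.52	0.07	-1.27	-0.51	-0.21
JANJ780101	AAindex	Average accessible surface area	27.8	15.5	60.6	68.2	25.5	24.5	50.7	22.8	103.0	27.6	33.5	60.1	51.5	68.7	94.7	42.0	45.0	23.7	34.7	55.2
KRIW790101	AAindex	Side chain interaction parameter	9.25	14.93	12.59	12.59	14.39	10.04	10.85	14.73	9.70	14.73	14.39	12.03	11.19	11.28	10.74	10.09	10.59	14.56	13.93	13.42
ZIMJ680102	AAindex	Bulkiness	11.50	13.46	11.68	13.57	19.80	3.40	13.69	21.40	15.71	21.40	16.25	12.82	17.43	14.45	14.28	9.47	15.77	21.57	21.67	18.03
ONEK900102	AAindex	Helix formation parameters (delta delta G)	-0.77	-0.23	-0.15	-0.27	-0.41	0.00	-0.06	-0.23	-0.65	-0.62	-0.50	-0.07	3.00	-0.33	-0.68	-0.35	-0.11	-0.14	-0.45	-0.17
FAU_STERIC	Fauchere	Steric parameter	1.28	1.77	1.60	1.56	2.94	0.00	2.99	4.19	1.89	2.59	2.35	1.60	2.67	1.56	2.34	1.31	3.03	3.67	3.21	2.94
FAU_POLARIZ	Fauchere	Polarizability	0.05	0.13	0.11	0.15	0.29	0.00	0.23	0.19	0.22	0.19	0.22	0.13	0.00	0.18	0.29	0.06	0.11	0.14	0.41	0.30
FAU_VOLUME	Fauchere	Volume	1.00	2.43	2.78	3.78	5.89	0.00	4.66	4.00	4.77	4.00	4.43	2.95	2.72	3.95	6.13	1.60	2.60	3.00	8.08	6.47
FAU_PI	Fauchere	Isoelectric point	6.11	6.35	2.95	3.09	5.67	6.07	7.69	6.04	9.99	6.04	5.71	6.52	6.80	5.65	10.74	5.70	5.60	6.02	5.94	5.66
FAU_HELIX	Fauchere	Helix probability	0.42	0.17	0.25	0.42	0.30	0.13	0.27	0.30	0.32	0.39	0.38	0.21	0.13	0.36	0.36	0.20	0.21	0.27	0.32	0.25
FAU_SHEET	Fauchere	Sheet probability	0.23	0.41	0.20	0.21	0.38	0.15	0.30	0.45	0.27	0.31	0.32	0.22	0.34	0.25	0.25	0.28	0.36	0.49	0.42	0.41
FAU_HYDRO	Fauchere	Hydrophobicity	0.31	1.54	-0.77	-0.64	1.79	0.00	0.13	1.80	-0.99	1.70	1.23	-0.60	0.72	-0.22	-1.01	-0.04	0.26	1.22	2.25	0.96
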