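srna_id	direction	fc_3h	fc_12h	fc_24h	fc_48h	fc_72h	q	r_reported
NC-181	up	1.52	3.31	3.52	3.72	3.74	5.09e-8	0.98
NC-1321	up	0.40	1.35	1.02	1.53	1.66	5.42e-6	0.90
NC-265	up	0.27	0.48	0.48	1.39	1.51	0.002	0.74
NC-350	up	0.36	1.04	0.41	0.82	1.49	5.13e-7	0.70
NC-117	down	-0.07	-0.90	-1.14	-0.50	-0.95	5.56e-4	NA
NC-1606	down	-0.13	-1.05	-0.43	-1.06	-1.10	1.03e-5	NA
NC-981	down	-0.40	-1.10	-0.48	-0.75	-0.57	6.84e-6	NA
NC-1637	down	0.20	-0.59	-0.54	-1.12	-1.13	6.60e-7	NA
NC-29	down	-0.69	-1.10	-1.79	-0.65	-1.04	7.26e-7	NA
NC-954	down	-0.22	-0.74	-0.37	-1.37	-1.20	4.43e-4	NA
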