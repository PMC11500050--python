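CHR	POS	ID	EA	SPANISH_P	SPANISH_OR	SPANISH_L95	SPANISH_U95	HARDCASTLE_P	HARDCASTLE_OR	HARDCASTLE_L95	HARDCASTLE_U95	META_P	META_OR	Q_P	I2
1	169088731	rs1200108	A	2.88E-01	0.87	0.67	1.13	4.52E-10	0.85	0.81	0.89	3.14E-10	0.85	0.89	0.00
1	175024486	rs6669560	T	7.00E-01	1.06	0.79	1.41	2.92E-09	1.17	1.11	1.23	2.42E-09	1.17	0.50	0.00
1	207808074	rs761276	A	2.47E-02	0.74	0.57	0.96	8.02E-09	0.87	0.83	0.91	7.55E-10	0.87	0.23	29.29
2	141120826	rs116792882	T	9.70E-02	5.47	0.74	40.72	4.82E-10	0.5	0.41	0.62	1.23E-09	0.51	0.02	81.47
3	29352153	rs11129361	A	6.27E-02	1.3	0.99	1.71	2.19E-07	1.15	1.09	1.21	3.26E-08	1.15	0.39	0.00
3	172279709	rs4894414	T	5.61E-01	1.11	0.79	1.56	1.21E-26	1.36	1.28	1.43	6.46E-27	1.35	0.25	25.80
5	53312130	rs252035	T	1.85E-01	0.83	0.62	1.1	7.79E-18	0.79	0.75	0.84	4.58E-19	0.79	0.76	0.00
5	122087230	rs2731657	A	6.41E-01	0.94	0.72	1.23	1.98E-20	0.79	0.75	0.83	2.34E-20	0.79	0.21	35.32
6	39586825	rs10947821	T	7.03E-02	1.33	0.98	1.82	1.30E-07	1.18	1.11	1.26	3.34E-08	1.19	0.45	0.00
6	50953889	rs6904450	A	7.83E-01	0.95	0.68	1.33	6.44E-11	0.83	0.78	0.88	1.76E-10	0.83	0.42	0.00
6	51742973	rs9382005	C	9.55E-01	1.01	0.77	1.31	2.31E-09	0.86	0.82	0.9	4.94E-09	0.86	0.25	24.65
6	75061719	rs118043261	A	5.65E-04	2.46	1.48	4.11	1.35E-14	1.72	1.5	1.98	8.46E-17	1.76	0.19	43.01
6	88852991	rs1321085	A	1.55E-01	1.29	0.91	1.83	1.00E-07	1.17	1.1	1.24	4.61E-08	1.17	0.59	0.00
8	23524256	rs73228208	A	5.32E-02	0.69	0.48	1.01	7.01E-08	0.85	0.8	0.9	1.43E-08	0.85	0.29	11.59
8	94907003	rs7820818	A	4.39E-01	0.9	0.68	1.18	4.06E-10	0.85	0.81	0.9	1.73E-10	0.85	0.70	0.00
9	13555514	rs1556575	A	2.41E-01	0.84	0.62	1.13	3.06E-19	0.78	0.74	0.83	2.66E-20	0.78	0.65	0.00
9	100259252	rs2806689	T	2.47E-02	0.74	0.57	0.96	2.69E-07	0.88	0.84	0.93	1.71E-08	0.88	0.20	38.18
9	108684737	rs7859737	A	9.34E-01	1.01	0.78	1.32	3.59E-11	0.85	0.82	0.9	1.60E-11	0.85	0.20	38.54
9	134548237	rs3118518	A	1.61E-02	1.38	1.06	1.8	1.83E-28	1.31	1.25	1.37	1.06E-29	1.31	0.69	0.00
9	136967018	rs7019538	T	4.68E-01	0.91	0.71	1.17	2.69E-11	0.84	0.8	0.89	6.15E-12	0.84	0.55	0.00
10	53436353	rs117905623	T	8.65E-01	0.94	0.46	1.92	1.89E-08	0.68	0.6	0.78	1.87E-08	0.69	0.38	0.00
10	101064592	rs807037	C	2.54E-02	1.36	1.04	1.79	5.84E-08	1.15	1.1	1.22	1.93E-08	1.16	0.23	30.65
10	119068783	rs10886377	C	3.49E-01	0.88	0.66	1.16	6.29E-12	0.84	0.8	0.88	3.69E-12	0.84	0.77	0.00
11	791462	rs4963153	A	1.49E-02	1.39	1.07	1.8	3.62E-26	1.3	1.24	1.37	5.12E-27	1.30	0.64	0.00
11	47641380	rs7120548	T	2.77E-01	0.87	0.67	1.12	1.91E-07	0.87	0.83	0.92	3.26E-08	0.87	0.98	0.00
11	95575690	rs11021221	A	6.92E-01	0.92	0.61	1.38	1.49E-09	1.23	1.15	1.31	2.21E-09	1.22	0.17	47.12
12	14137583	rs17340879	T	4.16E-01	1.48	0.57	3.82	1.77E-09	0.61	0.52	0.72	6.08E-09	0.63	0.07	69.51
12	51362485	rs3782473	T	2.38E-01	1.21	0.88	1.68	6.60E-10	1.19	1.12	1.25	1.94E-10	1.19	0.90	0.00
13	40536133	rs2755238	T	6.02E-05	0.54	0.4	0.73	1.49E-34	0.63	0.59	0.68	6.72E-39	0.62	0.31	1.23
13	41324269	rs9566743	A	3.54E-05	0.47	0.33	0.67	1.86E-09	0.78	0.72	0.85	7.67E-12	0.76	0.01	86.37
13	73070755	rs17285550	A	6.05E-01	0.93	0.7	1.23	2.84E-12	0.83	0.79	0.88	7.40E-13	0.83	0.44	0.00
15	51072532	rs11634895	A	3.16E-01	0.87	0.66	1.14	7.88E-10	0.86	0.82	0.91	1.41E-10	0.86	0.93	0.00
15	67174959	rs12912045	T	2.77E-01	1.19	0.87	1.61	4.57E-26	0.73	0.69	0.78	2.61E-25	0.74	0.00	89.23
16	88265987	rs35542380	C	9.94E-02	1.27	0.96	1.68	4.32E-19	1.26	1.2	1.32	8.35E-20	1.26	0.97	0.00
17	5027076	rs12603055	C	6.64E-02	0.7	0.49	1.02	2.23E-14	0.79	0.74	0.84	3.48E-15	0.79	0.55	0.00
17	19748589	rs4646785	T	8.88E-01	1.02	0.74	1.41	9.01E-12	0.82	0.78	0.87	1.38E-11	0.83	0.18	44.40
17	31558198	rs56161228	A	4.48E-02	0.64	0.41	0.99	2.70E-10	0.81	0.76	0.86	5.58E-11	0.81	0.29	9.63
17	48518906	rs7225995	C	2.26E-02	1.44	1.05	1.96	6.63E-09	1.19	1.12	1.26	8.34E-10	1.20	0.24	26.24
17	50167170	rs12939159	C	8.87E-01	0.97	0.64	1.47	2.11E-08	0.82	0.77	0.88	1.08E-08	0.82	0.43	0.00
20	2095648	rs6106210	T	5.01E-01	1.1	0.83	1.46	2.85E-11	1.19	1.13	1.25	1.42E-11	1.19	0.60	0.00
21	28247396	rs118737	T	5.56E-01	1.1	0.81	1.49	1.11E-10	1.22	1.15	1.3	1.70E-10	1.22	0.51	0.00
22	20969069	rs756878	T	4.76E-02	1.31	1	1.72	4.01E-09	1.17	1.11	1.24	1.15E-09	1.18	0.41	0.00
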