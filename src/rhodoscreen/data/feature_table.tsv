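aa	hydropathy_kd	hydrophilicity_hw	hydrophobicity_eisenberg	hydrophobicity_fp	volume_zamyatnin	bulkiness_zimmerman	polarity_grantham	polarity_zimmerman	isoelectric_point	net_charge_ph7	molecular_weight	asa_tripeptide	flexibility_bp	helix_propensity_cf	sheet_propensity_cf	turn_propensity_cf	refractivity_jones	polarizability_charton
A	1.8	-0.5	0.62	0.31	88.6	11.50	8.1	0.00	6.00	0.0	89.09	115	0.357	1.42	0.83	0.66	4.34	0.046
R	-4.5	3.0	-2.53	-1.01	173.4	14.28	10.5	52.00	10.76	1.0	174.20	225	0.529	0.98	0.93	0.95	26.66	0.291
N	-3.5	0.2	-0.78	-0.60	114.1	12.82	11.6	3.38	5.41	0.0	132.12	160	0.463	0.67	0.89	1.56	13.28	0.134
D	-3.5	3.0	-0.90	-0.77	111.1	11.68	13.0	49.70	2.77	-1.0	133.10	150	0.511	1.01	0.54	1.46	12.00	0.105
C	2.5	-1.0	0.29	1.54	108.5	13.46	5.5	1.48	5.07	0.0	121.16	135	0.346	0.70	1.19	1.19	35.77	0.128
Q	-3.5	0.2	-0.85	-0.22	143.8	14.45	10.5	3.53	5.65	0.0	146.15	180	0.493	1.11	1.10	0.98	17.56	0.180
E	-3.5	3.0	-0.74	-0.64	138.4	13.57	12.3	49.90	3.22	-1.0	147.13	190	0.497	1.51	0.37	0.74	17.26	0.151
G	-0.4	0.0	0.48	0.00	60.1	3.40	9.0	0.00	5.97	0.0	75.07	75	0.544	0.57	0.75	1.56	0.00	0.000
H	-3.2	-0.5	-0.40	0.13	153.2	13.69	10.4	51.60	7.59	0.1	155.16	195	0.323	1.00	0.87	0.95	21.81	0.230
I	4.5	-1.8	1.38	1.80	166.7	21.40	5.2	0.13	6.02	0.0	131.17	175	0.462	1.08	1.60	0.47	19.06	0.186
L	3.8	-1.8	1.06	1.70	166.7	21.40	4.9	0.13	5.98	0.0	131.17	170	0.365	1.21	1.30	0.59	18.78	0.186
K	-3.9	3.0	-1.50	-0.99	168.6	15.71	11.3	49.50	9.74	1.0	146.19	200	0.466	1.16	0.74	1.01	21.29	0.219
M	1.9	-1.3	0.64	1.23	162.9	16.25	5.7	1.43	5.74	0.0	149.21	185	0.295	1.45	1.05	0.60	21.64	0.221
F	2.8	-2.5	1.19	1.79	189.9	19.80	5.2	0.35	5.48	0.0	165.19	210	0.314	1.13	1.38	0.60	29.40	0.290
P	-1.6	0.0	0.12	0.72	112.7	17.43	8.0	1.58	6.30	0.0	115.13	145	0.509	0.57	0.55	1.52	10.93	0.131
S	-0.8	0.3	-0.18	-0.04	89.0	9.47	9.2	1.67	5.68	0.0	105.09	115	0.507	0.77	0.75	1.43	6.35	0.062
T	-0.7	-0.4	-0.05	0.26	116.1	15.77	8.6	1.66	5.60	0.0	119.12	140	0.444	0.83	1.19	0.96	11.01	0.108
W	-0.9	-3.4	0.81	2.25	227.8	21.67	5.4	2.10	5.89	0.0	204.23	255	0.305	1.08	1.37	0.96	42.53	0.409
Y	-1.3	-2.3	0.26	0.96	193.6	18.03	6.2	1.61	5.66	0.0	181.19	230	0.420	0.69	1.47	1.14	31.53	0.298
V	4.2	-1.5	1.08	1.22	140.0	21.57	5.9	0.13	5.96	0.0	117.15	155	0.386	1.06	1.70	0.50	13.92	0.140
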