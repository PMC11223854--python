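residue	n_carbon	n_hydrogen	n_nitrogen	n_oxygen	n_sulfur	n_atoms	n_heavy_atoms	n_sidechain_heavy	residue_mass	volume_a3	asa_tripeptide_a2	hydropathy_kd	hydrophilicity_hw	hydrophobicity_consensus	hydrophobicity_octanol	interface_transfer_dg	net_charge_ph7	isoelectric_point	sidechain_pka	polarity_index	refractivity	flexibility	bulkiness	helix_propensity	sheet_propensity	turn_propensity	hbond_donors	hbond_acceptors	is_aromatic	is_aliphatic	is_polar	is_charged	is_tiny	is_beta_branched	n_rotatable_bonds	is_helix_breaker
A	3	5	1	1	0	10	5	1	71.08	88.6	113	1.8	-0.5	0.62	0.31	-0.17	0	6	0	8.1	4.34	0.36	11.5	1.42	0.83	0.66	0	0	0	1	0	0	1	0	0	0
C	3	5	1	1	1	11	6	2	103.14	108.5	140	2.5	-1	0.29	1.54	0.24	0	5.07	8.3	5.5	35.77	0.35	13.46	0.7	1.19	1.19	1	0	0	0	1	0	1	0	1	0
D	4	5	1	3	0	13	8	4	115.09	111.1	151	-3.5	3	-0.9	-0.77	-1.23	-1	2.77	3.65	13	12	0.51	11.68	1.01	0.54	1.46	0	4	0	0	1	1	0	0	2	0
E	5	7	1	3	0	16	9	5	129.12	138.4	183	-3.5	3	-0.74	-0.64	-2.02	-1	3.22	4.25	12.3	17.26	0.5	13.57	1.51	0.37	0.74	0	4	0	0	1	1	0	0	3	0
F	9	9	1	1	0	20	11	7	147.18	189.9	218	2.8	-2.5	1.19	1.79	1.13	0	5.48	0	5.2	29.4	0.31	19.8	1.13	1.38	0.6	0	0	1	0	0	0	0	0	2	0
G	2	3	1	1	0	7	4	0	57.05	60.1	85	-0.4	0	0.48	0	-0.01	0	5.97	0	9	0	0.54	3.4	0.57	0.75	1.56	0	0	0	0	0	0	1	0	0	1
H	6	7	3	1	0	17	10	6	137.14	153.2	194	-3.2	-0.5	-0.4	0.13	-0.96	0.1	7.59	6	10.4	21.81	0.32	13.69	1	0.87	0.95	1	1	1	0	1	1	0	0	2	0
I	6	11	1	1	0	19	8	4	113.16	166.7	182	4.5	-1.8	1.38	1.8	0.31	0	6.02	0	5.2	19.06	0.46	21.4	1.08	1.6	0.47	0	0	0	1	0	0	0	1	2	0
K	6	12	2	1	0	21	9	5	128.17	168.6	211	-3.9	3	-1.5	-0.99	-0.99	1	9.74	10.53	11.3	21.29	0.47	15.71	1.16	0.74	1.01	3	0	0	0	1	1	0	0	4	0
L	6	11	1	1	0	19	8	4	113.16	166.7	180	3.8	-1.8	1.06	1.7	0.56	0	5.98	0	4.9	18.78	0.37	21.4	1.21	1.3	0.59	0	0	0	1	0	0	0	0	2	0
M	5	9	1	1	1	17	8	4	131.19	162.9	204	1.9	-1.3	0.64	1.23	0.23	0	5.74	0	5.7	21.64	0.3	16.25	1.45	1.05	0.6	0	0	0	0	0	0	0	0	3	0
N	4	6	2	2	0	14	8	4	114.1	114.1	158	-3.5	0.2	-0.78	-0.6	-0.42	0	5.41	0	11.6	13.28	0.46	12.82	0.67	0.89	1.56	2	2	0	0	1	0	0	0	2	0
P	5	7	1	1	0	14	7	3	97.12	112.7	143	-1.6	0	0.12	0.72	-0.45	0	6.3	0	8	10.93	0.51	17.43	0.57	0.55	1.52	0	0	0	0	0	0	0	0	0	1
Q	5	8	2	2	0	17	9	5	128.13	143.8	189	-3.5	0.2	-0.85	-0.22	-0.58	0	5.65	0	10.5	17.56	0.49	14.45	1.11	1.1	0.98	2	2	0	0	1	0	0	0	3	0
R	6	12	4	1	0	23	11	7	156.19	173.4	241	-4.5	3	-2.53	-1.01	-0.81	1	10.76	12.48	10.5	26.66	0.53	14.28	0.98	0.93	0.95	5	0	0	0	1	1	0	0	4	0
S	3	5	1	2	0	11	6	2	87.08	89	122	-0.8	0.3	-0.18	-0.04	-0.13	0	5.68	0	9.2	6.35	0.51	9.47	0.77	0.75	1.43	1	2	0	0	1	0	1	0	1	0
T	4	7	1	2	0	14	7	3	101.1	116.1	146	-0.7	-0.4	-0.05	0.26	-0.14	0	5.6	0	8.6	11.01	0.44	15.77	0.83	1.19	0.96	1	2	0	0	1	0	1	1	1	0
V	5	9	1	1	0	16	7	3	99.13	140	160	4.2	-1.5	1.08	1.22	-0.07	0	5.96	0	5.9	13.92	0.39	21.57	1.06	1.7	0.5	0	0	0	1	0	0	0	1	1	0
W	11	10	2	1	0	24	14	10	186.21	227.8	259	-0.9	-3.4	0.81	2.25	1.85	0	5.89	0	5.4	42.53	0.31	21.67	1.08	1.37	0.96	1	0	1	0	0	0	0	0	2	0
Y	9	9	1	2	0	21	12	8	163.18	193.6	229	-1.3	-2.3	0.26	0.96	0.94	0	5.66	10.07	6.2	31.53	0.42	18.03	0.69	1.47	1.14	1	1	1	0	1	0	0	0	2	0
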