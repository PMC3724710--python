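symbol	name	a	c	d	e	f	g	h	i	k	l	m	n	p	q	r	s	t	v	w	y
H	Hydrophobicity (membrane buried helix)	0.61	1.07	0.46	0.47	2.02	0.07	0.61	2.22	1.15	1.53	1.18	0.06	1.95	0	0.6	0.05	0.05	1.32	2.65	1.88
P	Polarity	0	1.48	49.7	49.9	0.35	0	51.6	0.13	49.5	0.13	1.43	3.38	1.58	3.53	52	1.67	1.66	0.13	2.1	1.61
Z	Polarizability parameter	0.046	0.128	0.105	0.151	0.29	0	0.23	0.186	0.219	0.186	0.221	0.134	0.131	0.18	0.291	0.062	0.108	0.14	0.409	0.298
X	Normalized frequency of alpha-helix	0.486	0.2	0.288	0.538	0.318	0.12	0.4	0.37	0.402	0.42	0.417	0.193	0.208	0.418	0.262	0.2	0.272	0.379	0.462	0.161
V	Normalized van der Waals volume	1	2.43	2.78	3.78	5.89	0	4.66	4	4.77	4	4.43	2.95	2.72	3.95	6.13	1.6	2.6	3	8.08	6.47
S	alpha-NH chemical shifts	8.249	8.312	8.41	8.368	8.228	8.391	8.415	8.195	8.408	8.423	8.418	8.747	0	8.411	8.274	8.38	8.236	8.436	8.094	8.183
C	A parameter of charge transfer capability	0	0	1	1	0	1	0	0	0	0	0	1	0	0	0	0	0	0	0	0
K	The Kerr-constant increments	49.1	0	0	0	54.7	64.6	75.7	18.9	0	15.6	6.8	-3.6	43.8	20	133	44.4	31	29.5	70.5	0
B	Normalized hydrophobicity scales for beta-proteins	-0.08	0.76	-0.71	-1.31	1.53	-0.84	0.43	1.39	-0.09	1.24	1.27	-0.7	-0.01	-0.4	-0.09	-0.93	-0.59	1.09	2.25	1.53
F	Normalized frequency of beta-sheet	0.83	1.19	0.54	0.37	1.38	0.75	0.87	1.6	0.74	1.3	1.05	0.89	0.55	1.1	0.93	0.75	1.19	1.7	1.37	1.47
T	Normalized frequency of beta-turn	0.74	0.96	1.52	0.95	0.66	1.56	0.95	0.47	1.19	0.5	0.6	1.46	1.56	0.96	1.01	1.43	0.98	0.59	0.6	1.14
R	Normalized frequency of reverse turn, with weights	0.77	0.81	1.41	0.99	0.59	1.64	0.68	0.51	0.96	0.58	0.41	1.28	1.91	0.98	0.88	1.32	1.04	0.47	0.76	1.05
E	Size	2.5	3	2.5	5	6.5	0.5	6	5.5	7	5.5	6	5	5.5	6	7.5	3	5	5	7	7
A	Amino acid composition	8.6	2.9	5.5	6	3.6	8.4	2	4.5	6.6	7.4	1.7	4.3	5.2	3.9	4.9	7	6.1	6.6	1.3	3.4
f	Frequency of the 1st residue in turn	0.06	0.149	0.147	0.056	0.059	0.102	0.14	0.043	0.055	0.061	0.068	0.161	0.102	0.074	0.07	0.12	0.086	0.062	0.077	0.082
N	Spin-spin coupling constants 3JHalpha-NH	6.5	7.7	7	7	9.4	5.6	8	7	6.5	6.5	0	7.5	0	6	6.9	6.5	6.9	7	0	6.8
M	Relative mutability	100	20	106	102	41	49	66	96	56	40	94	134	56	93	65	120	97	74	18	41
D	Direction of hydrophobic moment	0	0.76	-0.98	-0.89	0.92	0	-0.75	0.99	-0.99	0.89	0.94	-0.86	0.22	-1	-0.96	-0.67	0.09	0.84	0.67	-0.93
W	Molecular weight	89.09	121.15	133.1	147.13	165.19	75.07	155.16	131.17	146.19	131.2	149.21	132.12	115.13	146.15	174.2	105.09	119.12	117.15	204.24	181.19
O	Optical rotation	1.8	-16.5	5.05	12	-34.5	0	-38.5	12.4	14.6	-11	-10	-5.6	-86.2	6.3	12.5	-7.5	-28	5.63	-33.7	-10
a	Aperiodic indices for alpha-proteins	0.8	0	1.6	0.4	1.2	2	0.96	0.85	0.94	0.8	0.39	1.1	2.1	1.6	0.96	1.3	0.6	0.8	0	1.8
b	Aperiodic indices for beta-proteins	1.1	1.05	1.41	1.4	0.6	1.3	0.85	0.67	0.94	0.52	0.69	1.57	1.77	0.81	0.93	1.13	0.88	0.58	0.62	0.41
c	Aperiodic indices for alpha/beta-proteins	0.93	0.92	1.22	1.05	0.71	1.45	0.96	0.58	0.91	0.59	0.6	1.36	1.67	0.83	1.01	1.25	1.08	0.62	0.68	0.98
U	Volume	31	55	54	83	132	3	96	111	119	111	105	56	32.5	85	124	32	61	84	170	136
I	Partition energy	0.1	-1.42	0.78	0.83	-2.12	0.33	-0.5	-1.13	1.4	-1.18	-1.59	0.48	0.73	0.95	1.91	0.52	0.07	-1.27	-0.51	-0.21
Q	Heat capacity	29.22	50.7	37.09	41.84	48.52	23.71	59.64	45	57.1	48.03	69.32	38.3	36.13	44.02	26.37	32.4	35.2	40.35	56.92	51.73
L	Absolute entropy	30.88	53.83	40.66	44.98	51.06	24.74	65.99	49.71	63.21	50.62	55.32	41.7	39.21	46.62	68.43	35.65	36.5	42.75	60	51.15
G	Average accessible surface area	27.8	15.5	60.6	68.2	25.5	24.5	50.7	22.8	103	27.6	33.5	60.1	51.5	68.7	94.7	42	45	23.7	34.7	55.2
J	Percentage of buried residues	51	74	19	16	58	52	34	66	3	60	52	22	25	16	5	35	30	64	49	24
Y	Percentage of exposed residues	15	5	50	55	10	10	34	13	85	16	20	49	45	56	67	32	32	14	17	41
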