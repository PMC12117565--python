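# Electron five-Gaussian form-factor coefficients.
# f(s) = sum_j a_j exp(-b_j s^2), s = sin(theta)/lambda = q/(4 pi) in 1/Angstrom,
# (equivalently s = q[1/nm]/(40 pi)); a in Angstrom, b in Angstrom^2.
# Neutral-atom rows: Peng five-Gaussian parameterization (valid to q ~ 250 1/nm).
# Group rows (CH..SH): five-Gaussian fits to the Debye-formula amplitude of the group.
# version 1
symbol	Z	a1	a2	a3	a4	a5	b1	b2	b3	b4	b5
H	1	0.0349	0.1201	0.197	0.0573	0.1195	0.5347	3.5867	12.3471	18.9525	38.6269
He	2	0.0317	0.0838	0.1526	0.1334	0.0164	0.2507	1.4751	4.4938	12.6646	31.1653
C	6	0.0893	0.2563	0.757	1.0487	0.3575	0.2465	1.71	6.4094	18.6113	50.2523
N	7	0.1022	0.3219	0.7982	0.8197	0.1715	0.2451	1.7481	6.1925	17.3894	48.1431
O	8	0.0974	0.2921	0.691	0.699	0.2039	0.2067	1.3815	4.6943	12.7105	32.4726
S	16	0.2497	0.5628	1.3899	2.1865	0.7715	0.2681	1.6711	7.0267	19.5377	50.3888
CH	7	0.1796	0.8554	1.75	0.05001	0.2037	73.76	5.399	27.15	0.1116	1.062
CH2	8	0.1575	0.8528	2.359	0.00496	0.1935	89.04	4.637	30.92	-0.344	0.6172
CH3	9	0.4245	0.4256	0.2008	2.884	0.16	4.092	4.094	74.32	33.65	0.4189
NH	8	0.1568	0.222	0.8391	1.469	0.05579	64.9	1.017	4.656	23.17	0.11
NH2	9	1.991	0.2351	0.8575	5.336	-5.147	25.94	74.54	3.893	0.3422	0.3388
NH3	10	-0.1646	0.2896	0.838	0.1736	2.668	168.7	147.3	3.546	0.4059	29.57
OH	9	0.1597	0.2445	0.8406	1.235	0.03234	53.82	0.7846	4.042	20.92	-0.01414
SH	17	-78.51	80.62	0.6401	2.665	0.2755	9.013	9.014	1.924	37.71	0.2941
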