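# Species properties: atomic number, mass (amu), excluded-volume radius (nm),
# constituent atoms (for groups; '-' for plain elements).
# Excluded volume V = (4/3) pi r^3. version 1
symbol	Z	mass	radius_nm	constituents
H	1	1.008	0.107	-
He	2	4.0026	0.14	-
C	6	12.011	0.1577	-
N	7	14.007	0.084	-
O	8	15.999	0.13	-
Na	11	22.99	0.186	-
Mg	12	24.305	0.16	-
P	15	30.974	0.111	-
S	16	32.06	0.168	-
Cl	17	35.45	0.175	-
K	19	39.098	0.227	-
Ca	20	40.078	0.197	-
Fe	26	55.845	0.126	-
Zn	30	65.38	0.139	-
Au	79	196.967	0.144	-
CH	7	13.0190	0.172656	C,H
CH2	8	14.0270	0.185392	C,H,H
CH3	9	15.0350	0.196584	C,H,H,H
NH	8	15.0150	0.122043	N,H
NH2	9	16.0230	0.144907	N,H,H
NH3	10	17.0310	0.162207	N,H,H,H
OH	9	17.0070	0.150694	O,H
SH	17	33.0680	0.181375	S,H
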