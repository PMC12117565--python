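# SYNTHETIC electron five-Gaussian rows, same convention as electron_ff.tsv.
# Generated by fitting five Gaussians (s in [0, 2.5] 1/Angstrom) to the
# Mott-Bethe transform of the embedded X-ray table (xray_ff.tsv).
# Shipped for convenience for elements not covered by electron_ff.tsv;
# expect a few-percent accuracy, not reference quality.
# version 1
symbol	Z	a1	a2	a3	a4	a5	b1	b2	b3	b4	b5
Na	11	0.140835	0.502415	0.765822	1.1267	1.96489	0.214885	1.55288	6.06024	30.6216	93.8699
Mg	12	0.142655	0.473456	0.71557	1.40612	2.15938	0.201018	1.38056	5.29485	22.0693	59.6955
P	15	0.171381	0.486547	0.975319	2.38115	1.44897	0.193077	1.25012	5.46127	17.6503	49.2554
Cl	17	0.171694	0.442018	1.00349	2.16826	1.07197	0.170784	1.06132	4.37585	12.8507	35.1628
K	19	0.272785	0.796855	2.31018	2.12075	3.37908	0.237998	1.85405	8.09815	37.6573	146.617
Ca	20	0.276519	0.830278	2.18902	3.19293	3.40184	0.22992	1.81132	7.51531	37.4178	115.932
Fe	26	0.273556	0.825588	1.58393	1.8443	2.40036	0.179776	1.31892	4.55538	17.2408	56.0245
Zn	30	0.290536	0.878621	1.34475	1.41824	1.86741	0.168579	1.1848	3.94944	13.9111	43.317
Au	79	0.649515	1.4784	2.42552	2.86046	2.61894	0.154979	0.938103	3.52883	9.48822	27.6945
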