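# X-ray form-factor coefficients as five Gaussians, units of electrons.
# f(s) = sum_j a_j exp(-b_j s^2), s = sin(theta)/lambda in 1/Angstrom.
# Rows are Cromer-Mann a1..a4,b1..b4,c with the constant c stored as a
# fifth zero-width Gaussian (a5=c, b5=0). f(0) = Z to <0.1% for all rows.
# version 1
symbol	Z	a1	a2	a3	a4	a5	b1	b2	b3	b4	b5
H	1	0.489918	0.262003	0.196767	0.049879	0.001305	20.6593	7.74039	49.5519	2.20159	0
He	2	0.8734	0.6309	0.3112	0.178	0.0064	9.1037	3.3568	22.9276	0.9821	0
C	6	2.31	1.02	1.5886	0.865	0.2156	20.8439	10.2075	0.5687	51.6512	0
N	7	12.2126	3.1322	2.0125	1.1663	-11.529	0.0057	9.8933	28.9975	0.5826	0
O	8	3.0485	2.2868	1.5463	0.867	0.2508	13.2771	5.7011	0.3239	32.9089	0
Na	11	4.7626	3.1736	1.2674	1.1128	0.676	3.285	8.8422	0.3136	129.424	0
Mg	12	5.4204	2.1735	1.2269	2.3073	0.8584	2.8275	79.2611	0.3808	7.1937	0
P	15	6.4345	4.1791	1.78	1.4908	1.1149	1.9067	27.157	0.526	68.1645	0
S	16	6.9053	5.2034	1.4379	1.5863	0.8669	1.4679	22.2151	0.2536	56.172	0
Cl	17	11.4604	7.1964	6.2556	1.6455	-9.5574	0.0104	1.1662	18.5194	47.7784	0
K	19	8.2186	7.4398	1.0519	0.8659	1.4228	12.7949	0.7748	213.187	41.6841	0
Ca	20	8.6266	7.3873	1.5899	1.0211	1.3751	10.4421	0.6599	85.7484	178.437	0
Fe	26	11.7695	7.3573	3.5222	2.3045	1.0369	4.7611	0.3072	15.3535	76.8805	0
Zn	30	14.0743	7.0318	5.1652	2.41	1.3041	3.2655	0.2333	10.3163	58.7097	0
Au	79	16.8819	18.5913	25.5582	5.86	12.0658	0.4611	8.6216	1.4826	36.3956	0
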