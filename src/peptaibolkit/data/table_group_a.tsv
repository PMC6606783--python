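name	M	M_Na	M_2Na	b_diag	y7	rt	R	R1	R2	R3	R4	R5	R6	R7	R8	R9	R10	R11	R12	R13	R14	R15	R16	R17	R18	R19	R20
Pept-A-Ia	1922	1945	984	1149	774	35.35	Ac	Aib	Ala	Aib	Ala	Aib	Ala	Gln	Aib	Vxx	Ala	Gly	Lxx	Aib	Pro	Vxx	Aib	Aib	Gln	Gln	Pheol
Pept-A-Ib	1922	1945	984	1149	774	36.88	Ac	Aib	Ala	Aib	Ala	Aib	Aib	Gln	Aib	Vxx	Ala	Gly	Vxx	Aib	Pro	Vxx	Aib	Aib	Gln	Gln	Pheol
Pept-A-IIa	1923	1946	984.5	1149	775	38.26	Ac	Aib	Ala	Aib	Ala	Aib	Ala	Gln	Aib	Vxx	Aib	Gly	Vxx	Aib	Pro	Vxx	Aib	Aib	Glu	Gln	Pheol
Pept-A-IIb	1923	1946	984.5	1149	775	37.46	Ac	Aib	Ala	Aib	Ala	Aib	Ala	Gln	Aib	Vxx	Ala	Gly	Lxx	Aib	Pro	Vxx	Aib	Aib	Glu	Gln	Pheol
Pept-A-IIIa	1936	1959	991	1149	788	39.82	Ac	Aib	Ala	Aib	Ala	Aib	Ala	Gln	Aib	Vxx	Aib	Gly	Vxx	Aib	Pro	Vxx	Aib	Vxx	Gln	Gln	Pheol
Pept-A-IIIb	1936	1959	991	1149	788	38.17	Ac	Aib	Ala	Aib	Ala	Aib	Ala	Gln	Aib	Vxx	Ala	Gly	Lxx	Aib	Pro	Vxx	Aib	Vxx	Gln	Gln	Pheol
Pept-A-IIIc	1936	1959	991	1149	788	39.89	Ac	Aib	Ala	Aib	Ala	Aib	Aib	Gln	Aib	Vxx	Ala	Gly	Vxx	Aib	Pro	Vxx	Aib	Vxx	Gln	Gln	Pheol
Pept-A-IVa	1936	1959	991	1163	774	40.21	Ac	Aib	Ala	Aib	Ala	Aib	Ala	Gln	Aib	Vxx	Aib	Gly	Lxx	Aib	Pro	Vxx	Aib	Aib	Gln	Gln	Pheol
Pept-A-IVb	1936	1959	991	1163	774	40.18	Ac	Aib	Ala	Aib	Ala	Aib	Ala	Gln	Aib	Lxx	Ala	Gly	Lxx	Aib	Pro	Vxx	Aib	Aib	Gln	Gln	Pheol
Pept-A-Va	1950	1973	998	1177	774	40.73	Ac	Aib	Ala	Aib	Ala	Aib	Aib	Gln	Aib	Vxx	Aib	Gly	Lxx	Aib	Pro	Vxx	Aib	Aib	Gln	Gln	Pheol
Pept-A-Vb	1950	1973	998	1177	774	41.40	Ac	Aib	Ala	Aib	Ala	Aib	Ala	Gln	Aib	Lxx	Aib	Gly	Lxx	Aib	Pro	Vxx	Aib	Aib	Gln	Gln	Pheol
Pept-A-VIa	1937	1960	991.5	1163	775	41.46	Ac	Aib	Ala	Aib	Ala	Aib	Ala	Gln	Aib	Vxx	Aib	Gly	Lxx	Aib	Pro	Vxx	Aib	Aib	Glu	Gln	Pheol
Pept-A-VIb	1937	1960	991.5	1163	775	41.50	Ac	Aib	Ala	Aib	Ala	Aib	Ala	Gln	Aib	Lxx	Ala	Gly	Lxx	Aib	Pro	Vxx	Aib	Aib	Glu	Gln	Pheol
Pept-A-VIIa	1936	1959	991	1163	774	41.00	Ac	Aib	Ala	Aib	Ala	Aib	Ala	Gln	Aib	Vxx	Aib	Gly	Lxx	Aib	Pro	Vxx	Aib	Aib	Gln	Gln	Pheol
Pept-A-VIIb	1936	1959	991	1163	774	42.53	Ac	Aib	Ala	Vxx	Ala	Aib	Ala	Gln	Aib	Vxx	Ala	Gly	Lxx	Aib	Pro	Vxx	Aib	Aib	Gln	Gln	Pheol
Pept-A-VIIIa	1950	1973	998	1177	774	42.29	Ac	Aib	Ala	Vxx	Ala	Aib	Ala	Gln	Aib	Lxx	Ala	Gly	Lxx	Aib	Pro	Vxx	Aib	Aib	Gln	Gln	Pheol
Pept-A-VIIIb	1950	1973	998	1177	774	42.46	Ac	Aib	Ala	Vxx	Ala	Aib	Ala	Gln	Aib	Vxx	Aib	Gly	Lxx	Aib	Pro	Vxx	Aib	Aib	Gln	Gln	Pheol
Pept-A-IXa	1950	1973	998	1163	788	42.76	Ac	Aib	Ala	Aib	Ala	Aib	Ala	Gln	Aib	Vxx	Aib	Gly	Lxx	Aib	Pro	Vxx	Aib	Vxx	Gln	Gln	Pheol
Pept-A-IXb	1950	1973	998	1163	788	42.84	Ac	Aib	Ala	Aib	Ala	Aib	Ala	Gln	Aib	Lxx	Ala	Gly	Lxx	Aib	Pro	Vxx	Aib	Vxx	Gln	Gln	Pheol
Pept-A-Xa	1964	1987	1005	1177	788	43.28	Ac	Aib	Ala	Aib	Ala	Aib	Aib	Gln	Aib	Vxx	Aib	Gly	Lxx	Aib	Pro	Vxx	Aib	Vxx	Gln	Gln	Pheol
Pept-A-Xb	1964	1987	1005	1177	788	42.89	Ac	Aib	Ala	Aib	Ala	Aib	Ala	Gln	Aib	Lxx	Aib	Gly	Lxx	Aib	Pro	Vxx	Aib	Vxx	Gln	Gln	Pheol
Pept-A-XIa	1951	1974	998.5	1177	775	43.60	Ac	Aib	Ala	Vxx	Ala	Aib	Ala	Gln	Aib	Vxx	Aib	Gly	Lxx	Aib	Pro	Vxx	Aib	Aib	Glu	Gln	Pheol
Pept-A-XIb	1951	1974	998.5	1177	775	43.60	Ac	Aib	Ala	Aib	Ala	Aib	Aib	Gln	Aib	Vxx	Aib	Gly	Lxx	Aib	Pro	Vxx	Aib	Aib	Glu	Gln	Pheol
Pept-A-XIc	1951	1974	998.5	1177	775	43.62	Ac	Aib	Ala	Vxx	Ala	Aib	Ala	Gln	Aib	Lxx	Ala	Gly	Lxx	Aib	Pro	Vxx	Aib	Aib	Glu	Gln	Pheol
Pept-A-XII	1937	1960	991.5	1163	775	42.81	Ac	Aib	Ala	Aib	Ala	Aib	Ala	Gln	Aib	Lxx	Ala	Gly	Lxx	Aib	Pro	Vxx	Aib	Aib	Glu	Gln	Pheol
Pept-A-XIIIa	1951	1974	998.5	1163	789	44.14	Ac	Aib	Ala	Aib	Ala	Aib	Ala	Gln	Aib	Vxx	Aib	Gly	Lxx	Aib	Pro	Vxx	Aib	Vxx	Glu	Gln	Pheol
Pept-A-XIIIb	1951	1974	998.5	1163	789	44.16	Ac	Aib	Ala	Aib	Ala	Aib	Ala	Gln	Aib	Lxx	Ala	Gly	Lxx	Aib	Pro	Vxx	Aib	Vxx	Glu	Gln	Pheol
Pept-A-XIVa	1965	1988	1005.5	1177	789	44.22	Ac	Aib	Ala	Aib	Ala	Aib	Aib	Gln	Aib	Lxx	Ala	Gly	Lxx	Aib	Pro	Vxx	Aib	Vxx	Glu	Gln	Pheol
Pept-A-XIVb	1964	1987	1005	1177	788	44.13	Ac	Aib	Ala	Aib	Ala	Aib	Aib	Gln	Aib	Vxx	Aib	Gly	Lxx	Aib	Pro	Vxx	Aib	Vxx	Gln	Gln	Pheol
Pept-A-XVa	1950	1973	998	1163	788	45.00	Ac	Aib	Ala	Aib	Ala	Aib	Ala	Gln	Aib	Vxx	Aib	Gly	Lxx	Aib	Pro	Vxx	Aib	Vxx	Gln	Gln	Pheol
Pept-A-XVb	1964	1987	1005	1177	788	44.74	Ac	Aib	Ala	Aib	Ala	Aib	Aib	Gln	Aib	Lxx	Ala	Gly	Lxx	Aib	Pro	Vxx	Aib	Vxx	Gln	Gln	Pheol
Pept-A-XVIa	1950	1973	998	1177	774	45.21	Ac	Aib	Ala	Aib	Ala	Aib	Aib	Gln	Aib	Vxx	Aib	Gly	Lxx	Aib	Pro	Vxx	Aib	Aib	Gln	Gln	Pheol
Pept-A-XVIb	1950	1973	998	1177	774	45.33	Ac	Aib	Ala	Aib	Ala	Aib	Aib	Gln	Aib	Lxx	Ala	Gly	Lxx	Aib	Pro	Vxx	Aib	Aib	Gln	Gln	Pheol
Pept-A-XVIIa	1964	1987	1005	1177	788	46.21	Ac	Aib	Ala	Aib	Ala	Aib	Aib	Gln	Aib	Vxx	Aib	Gly	Lxx	Aib	Pro	Vxx	Aib	Vxx	Gln	Gln	Pheol
Pept-A-XVIIb	1950	1973	998	1163	788	46.18	Ac	Aib	Ala	Aib	Ala	Aib	Ala	Gln	Aib	Vxx	Aib	Gly	Lxx	Aib	Pro	Vxx	Aib	Vxx	Gln	Gln	Pheol
Pept-A-XVIII	1978	2001	1012	1191	788	46.36	Ac	Aib	Ala	Vxx	Ala	Aib	Aib	Gln	Aib	Vxx	Aib	Gly	Lxx	Aib	Pro	Vxx	Aib	Vxx	Gln	Gln	Pheol
Pept-A-XIXa	1951	1974	998.5	1177	775	46.67	Ac	Aib	Ala	Aib	Ala	Aib	Aib	Gln	Aib	Vxx	Aib	Gly	Lxx	Aib	Pro	Vxx	Aib	Aib	Glu	Gln	Pheol
Pept-A-XIXb	1951	1974	998.5	1177	775	46.86	Ac	Aib	Ala	Aib	Ala	Aib	Aib	Gln	Aib	Lxx	Ala	Gly	Lxx	Aib	Pro	Vxx	Aib	Aib	Glu	Gln	Pheol
Pept-A-XX	1964	1987	1005	1191	774	47.30	Ac	Aib	Ala	Vxx	Ala	Aib	Aib	Gln	Aib	Vxx	Aib	Gly	Lxx	Aib	Pro	Vxx	Aib	Aib	Gln	Gln	Pheol
Pept-A-XXIa	1964	1987	1005	1177	788	47.85	Ac	Aib	Ala	Aib	Ala	Aib	Aib	Gln	Aib	Vxx	Aib	Gly	Lxx	Aib	Pro	Vxx	Aib	Vxx	Gln	Gln	Pheol
Pept-A-XXIb	1964	1987	1005	1177	788	47.75	Ac	Aib	Ala	Aib	Ala	Aib	Aib	Gln	Aib	Lxx	Ala	Gly	Lxx	Aib	Pro	Vxx	Aib	Vxx	Gln	Gln	Pheol
Pept-A-XXIIa	1964	1987	1005	1191	774	48.93	Ac	Aib	Ala	Vxx	Ala	Aib	Aib	Gln	Aib	Vxx	Aib	Gly	Lxx	Aib	Pro	Vxx	Aib	Aib	Gln	Gln	Pheol
Pept-A-XXIIb	1964	1987	1005	1191	774	48.79	Ac	Aib	Ala	Aib	Ala	Aib	Aib	Gln	Aib	Lxx	Aib	Gly	Lxx	Aib	Pro	Vxx	Aib	Aib	Gln	Gln	Pheol
Pept-A-XXIII	1965	1988	1005.5	1177	789	49.13	Ac	Aib	Ala	Aib	Ala	Aib	Aib	Gln	Aib	Vxx	Aib	Gly	Lxx	Aib	Pro	Vxx	Aib	Vxx	Glu	Gln	Pheol
Pept-A-XXIV	1978	2001	1012	1191	788	49.89	Ac	Aib	Ala	Vxx	Ala	Aib	Aib	Gln	Aib	Vxx	Aib	Gly	Lxx	Aib	Pro	Vxx	Aib	Vxx	Gln	Gln	Pheol
Pept-A-XXVa	1964	1987	1005	1177	788	49.65	Ac	Aib	Ala	Aib	Ala	Aib	Aib	Gln	Aib	Vxx	Aib	Gly	Lxx	Aib	Pro	Vxx	Aib	Vxx	Gln	Gln	Pheol
Pept-A-XXVb	1978	2001	1012	1191	788	49.72	Ac	Aib	Ala	Aib	Ala	Aib	Aib	Gln	Aib	Lxx	Aib	Gly	Lxx	Aib	Pro	Vxx	Aib	Vxx	Gln	Gln	Pheol
Pept-A-XXVIa	1978	2001	1012	1191	788	51.29	Ac	Aib	Ala	Vxx	Ala	Aib	Aib	Gln	Aib	Vxx	Aib	Gly	Lxx	Aib	Pro	Vxx	Aib	Vxx	Gln	Gln	Pheol
Pept-A-XXVIb	1978	2001	1012	1191	788	50.85	Ac	Aib	Ala	Aib	Ala	Aib	Aib	Gln	Aib	Lxx	Aib	Gly	Lxx	Aib	Pro	Vxx	Aib	Vxx	Gln	Gln	Pheol
Pept-A-XXVIIa	1965	1988	1005.5	1177	789	51.44	Ac	Aib	Ala	Aib	Ala	Aib	Aib	Gln	Aib	Vxx	Aib	Gly	Lxx	Aib	Pro	Vxx	Aib	Vxx	Glu	Gln	Pheol
Pept-A-XXVIIb	1978	2001	1012	1191	788	51.59	Ac	Aib	Ala	Aib	Ala	Aib	Aib	Gln	Aib	Lxx	Aib	Gly	Lxx	Aib	Pro	Vxx	Aib	Vxx	Gln	Gln	Pheol
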