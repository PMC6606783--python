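name	M	M_Na	M_2Na	b_diag	y7	rt	R	R1	R2	R3	R4	R5	R6	R7	R8	R9	R10	R11	R12	R13	R14	R15	R16	R17	R18	R19	R20
Brevicelsin-I	1851	1874	948.5	1078	774	28.72	Ac	Aib	Ala	Aib	Ala	Aib	-	Gln	Aib	Lxx	Aib	Gly	Aib	Aib	Pro	Vxx	Aib	Aib	Gln	Gln	Pheol
Brevicelsin-II	1865	1888	955.5	1092	774	29.98	Ac	Aib	Ala	Vxx	Ala	Aib	-	Gln	Aib	Lxx	Aib	Gly	Aib	Aib	Pro	Vxx	Aib	Aib	Gln	Gln	Pheol
Brevicelsin-III	1852	1875	949	1078	775	30.56	Ac	Aib	Ala	Aib	Ala	Aib	-	Gln	Aib	Lxx	Aib	Gly	Aib	Aib	Pro	Vxx	Aib	Aib	Glu	Gln	Pheol
Brevicelsin-IV	1865	1888	955.5	1078	788	31.82	Ac	Aib	Ala	Aib	Ala	Aib	-	Gln	Aib	Lxx	Aib	Gly	Aib	Aib	Pro	Vxx	Aib	Vxx	Gln	Gln	Pheol
Brevicelsin-V	1879	1902	962.5	1092	788	32.82	Ac	Aib	Ala	Aib	Ala	Vxx	-	Gln	Aib	Lxx	Aib	Gly	Aib	Aib	Pro	Vxx	Aib	Vxx	Gln	Gln	Pheol
Brevicelsin-VI	1865	1888	955.5	1092	774	33.20	Ac	Aib	Ala	Aib	Ala	Vxx	-	Gln	Aib	Lxx	Aib	Gly	Aib	Aib	Pro	Vxx	Aib	Aib	Gln	Gln	Pheol
Brevicelsin-VII	1866	1889	956	1078	789	33.65	Ac	Aib	Ala	Aib	Ala	Aib	-	Gln	Aib	Lxx	Aib	Gly	Aib	Aib	Pro	Vxx	Aib	Vxx	Glu	Gln	Pheol
Brevicelsin-VIII	1879	1902	962.5	1092	788	36.19	Ac	Aib	Ala	Aib	Ala	Vxx	-	Gln	Aib	Lxx	Aib	Gly	Aib	Aib	Pro	Vxx	Aib	Vxx	Gln	Gln	Pheol
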