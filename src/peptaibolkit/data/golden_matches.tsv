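candidate	reference	expected_notation	expected_distance
Pept-A-Ib	Trichoaureocin 1d	[Lxx]^12 → [Vxx]^12	1
Pept-A-IIa	Longibrachin B II	[Lxx]^12 → [Vxx]^12	1
Pept-A-IIIa	Paracelsin F	[Aib]^12 → [Vxx]^12	1
Pept-A-IIIb	Longibrachin A II	[Aib]^10 → [Ala]^10	1
Pept-A-VIb	Longibrachin B II	[Vxx]^9 → [Lxx]^9; [Aib]^10 → [Ala]^10	2
Pept-A-VIIIb	Longibrachin A I	[Aib]^3 → [Vxx]^3	1
Pept-A-XIa	Longibrachin B II	[Aib]^3 → [Vxx]^3	1
Pept-A-XIc	Longibrachin B II	[Aib]^3 → [Vxx]^3; [Vxx]^9 → [Lxx]^9; [Aib]^10 → [Ala]^10	3
Pept-A-XVIII	Longibrachin A IV	[Aib]^3 → [Vxx]^3	1
Pept-A-XX	Longibrachin A III	[Aib]^3 → [Vxx]^3	1
Pept-B-I	Paracelsin B	[Aib]^3 → [Ala]^3	1
Pept-B-IV	Paracelsin H	[Aib]^3 → [Ala]^3	1
Pept-B-XXVI	Paracelsin D	[Aib]^3 → [Vxx]^3	1
Pept-B-XXVIII	Paracelsin D	[Aib]^5 → [Vxx]^5	1
Pept-B-LIX	Paracelsin H	[Aib]^3 → [Vxx]^3; [Aib]^5 → [Vxx]^5; [Ala]^6 → [Vxx]^6	3
Brevicelsin-I	Paracelsin B	Δ[Ala]^6	1
Brevicelsin-II	Paracelsin B	[Aib]^3 → [Vxx]^3; Δ[Ala]^6	2
Brevicelsin-IV	Paracelsin H	Δ[Ala]^6	1
Brevicelsin-V	Paracelsin H	[Aib]^5 → [Vxx]^5; Δ[Ala]^6	2
Brevicelsin-VI	Paracelsin B	[Aib]^5 → [Vxx]^5; Δ[Ala]^6	2
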