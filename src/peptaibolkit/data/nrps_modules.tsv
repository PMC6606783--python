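species	position	signature	predicted_a	predicted_b	detected
T. reesei	1	DLGYLAGV	Aib;Iva	Iva	Aib
T. citrinoviride	1	DLGYLAGV	Aib;Iva	Iva	Aib
T. longibrachiatum	1	DLGYLAGV	Aib;Iva	Iva	Aib
T. parareesei	1	DLGYLAGV	Aib;Iva	Iva	Aib
T. reesei	2	DILFNGLI	Ala		Ala
T. citrinoviride	2	DILFNGLI	Ala		Ala
T. longibrachiatum	2	DILFNGLI	Ala		Ala
T. parareesei	2	DILFNGLI	Ala		Ala
T. reesei	3	DLGFLAGV	Aib;Iva	Iva	Aib;Ala
T. citrinoviride	3	DLGFLAGV	Aib;Iva	Iva	Aib
T. longibrachiatum	3	DLGFLAGV	Aib;Iva	Iva	Aib;Iva
T. parareesei	3	DLGFLAGV	Aib;Iva	Iva	Aib
T. reesei	4	DVGFVAGV	Aib;Iva	ala	Ala
T. citrinoviride	4	DVGFVAGV	Aib;Iva	ala	Ala
T. longibrachiatum	4	DVGFVAGV	Aib;Iva	ala	Ala
T. parareesei	4	DVGFVAGV	Aib;Iva	ala	Ala
T. reesei	5	DLGFLAGV	Aib;Iva	Iva	Aib
T. citrinoviride	5	DLGFLAGV	Aib;Iva	Iva	Aib
T. longibrachiatum	5	DLGFLAGV	Aib;Iva	Iva	Aib
T. parareesei	5	DLGFLAGV	Aib;Iva	Iva	Aib
T. reesei	6	DVGCIEGV	Aib;Iva	Iva	Ala
T. citrinoviride	6	DVGCIEGV	Aib;Iva	Iva	Ala
T. longibrachiatum	6	DVGCIAGV	Aib;Iva		Ala
T. parareesei	6	DVGCIEGV	Aib;Iva	Iva	Ala
T. reesei	7	DGGMVGGN	Gln	Gln	Gln
T. citrinoviride	7	DGGMVGGN	Gln	Gln	Gln
T. longibrachiatum	7	DGGMVGGN	Gln	Gln	Gln
T. parareesei	7	DGGMVGGN	Gln	Gln	Gln
T. reesei	8	DLGYLAGV	Aib;Iva	Iva	Aib
T. citrinoviride	8	DLGYLAGV	Aib;Iva	Iva	Aib
T. longibrachiatum	8	DLGYLAGV	Aib;Iva	Iva	Aib
T. parareesei	8	DLGYLAGV	Aib;Iva	Iva	Aib
T. reesei	9	DAFLIGGV	Aib;Iva	Leu	Iva;Ile
T. citrinoviride	9	DAFLIGGV	Aib;Iva	Leu	Iva;Ile
T. longibrachiatum	9	DAFLLGAV	Ala	Als	Iva;Ile
T. parareesei	9	DAFLIGAV	Aib;Iva	Leu	Iva;Ile
T. reesei	10	DLGYLAGV	Aib;Iva	Iva	Aib
T. citrinoviride	10	DLGYLAGV	Aib;Iva	Iva	Aib
T. longibrachiatum	10	DLGYLAGV	Aib;Iva	Iva	Aib
T. parareesei	10	DLGYLAGV	Aib;Iva	Iva	Aib
T. reesei	11	DVGYLIAV	Aib;Iva		Gly
T. citrinoviride	11	DVGYLIAV	Aib;Iva		Gly
T. longibrachiatum	11	DVGYLIAV	Aib;Iva		Gly
T. parareesei	11	DVGYLIAV	Aib;Iva		Gly
T. reesei	12	DLGYLAG-	Aib;Iva		Ile;Iva;Aib
T. citrinoviride	12	DLGYLAGV	Aib;Iva	ala	Ile
T. longibrachiatum	12	DFGFLGAV	Aib;Iva		Ile;Iva
T. parareesei	12	DLAYLAG-	Aib;Iva		Ala;Iva;Aib
T. reesei	13	DLGFLAGV	Aib;Iva	Iva	Aib
T. citrinoviride	13	DLGFLAGV	Aib;Iva	Iva	Aib
T. longibrachiatum	13	DLGFLAGV	Aib;Iva	Iva	Aib
T. parareesei	13	DLGYLAGV	Aib;Iva	Iva	Aib
T. reesei	14	DVLFCGLI	Pro		Pro
T. citrinoviride	14	DVLFCGLI	Pro		Pro
T. longibrachiatum	14	DVLFCGLI	Pro		Pro
T. parareesei	14	DVLFCGLI	Pro		Pro
T. reesei	15	DAGMIIGV	Aib;Iva	Iva	Iva
T. citrinoviride	15	DAGMIIGV	Aib;Iva	Iva	Iva
T. longibrachiatum	15	DAGMIIGV	Aib;Iva	Iva	Iva
T. parareesei	15	DAGMIIGV	Aib;Iva	Iva	Iva
T. reesei	16	DLGFLAGV	Aib;Iva	Iva	Aib
T. citrinoviride	16	DLGFLAGV	Aib;Iva	Iva	Aib
T. longibrachiatum	16	DLGFLAGV	Aib;Iva	Iva	Aib
T. parareesei	16	DLGFLAGV	Aib;Iva	Iva	Aib
T. reesei	17	DMGWFAG-	Aib;Iva	Iva	Aib;Iva
T. citrinoviride	17	DMGWFAGV	Aib;Iva	Iva	Aib;Iva
T. longibrachiatum	17	DMGWFAGV	Aib;Iva	Iva	Aib;Iva
T. parareesei	17	DMGWFAG-	Aib;Iva	Iva	Aib;Iva
T. reesei	18	DGGMVGGN	Gln	Gln	Glu;Gln
T. citrinoviride	18	DGGMVGGN	Gln	Gln	Glu;Gln
T. longibrachiatum	18	DGGMVGGN	Gln	Gln	Glu;Gln
T. parareesei	18	DGGMVGGN	Gln	Gln	Glu;Gln
T. reesei	19	DGGMVGGN	Gln	Gln	Gln
T. citrinoviride	19	DGGMVGGN	Gln	Gln	Gln
T. longibrachiatum	19	DGGMVGGN	Gln	Gln	Gln
T. parareesei	19	DGGMIGGN	Gln	Gln	Gln
T. reesei	20	DAAFIMGV			Pheol
T. citrinoviride	20	DAAFIMGV			Pheol
T. longibrachiatum	20	DAAFIMGV			Pheol
T. parareesei	20	DAAFIMGV			Pheol
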