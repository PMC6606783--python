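# peptaibolkit residue registry v1
# code	mono_mass	unit_class	collapse_class
Ac	42.01057	n_cap	Ac
Gly	57.02146	internal_residue	Gly
Ala	71.03711	internal_residue	Ala
Aib	85.05276	internal_residue	Aib
Ser	87.03203	internal_residue	Ser
Pro	97.05276	internal_residue	Pro
Val	99.06841	internal_residue	Vxx
Iva	99.06841	internal_residue	Vxx
Vxx	99.06841	internal_residue	Vxx
Thr	101.04768	internal_residue	Thr
Leu	113.08406	internal_residue	Lxx
Ile	113.08406	internal_residue	Lxx
Lxx	113.08406	internal_residue	Lxx
Gln	128.05858	internal_residue	Gln
Glu	129.04259	internal_residue	Glu
Alaol	75.06841	c_terminal_alcohol	Alaol
Prool	101.08406	c_terminal_alcohol	Prool
Valol	103.09971	c_terminal_alcohol	Valol
Ileol	117.11536	c_terminal_alcohol	Lxxol
Leuol	117.11536	c_terminal_alcohol	Lxxol
Lxxol	117.11536	c_terminal_alcohol	Lxxol
Pheol	151.09971	c_terminal_alcohol	Pheol
Tyrol	167.09463	c_terminal_alcohol	Tyrol
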