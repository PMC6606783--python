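# Packaged fixtures

* `residues.tsv` — versioned residue-mass registry (code, monoisotopic
  mass, unit class, collapse class). Masses are fixed here; nothing is
  looked up at runtime.
* `table_group_a.tsv`, `table_group_b.tsv`, `table_group_c.tsv` — compound
  tables for peptaibol groups A (51 rows), B (77) and C (8 brevicelsins),
  transcribed from published compound tables: per row the printed
  M / [M+Na]+ / [M+2Na]2+ / b-diagnostic / y7 values, retention time, the
  N-cap column R and residues R1–R20 (`-` marks the R6 vacancy of the
  19-residue group C chains). Emphasis markup of the source was stripped;
  no cell values were altered.
* `reference_catalog.csv` — 71 published peptaibol chains (name, chain,
  citation) implied by the identity annotations of the compound tables.
  Where an annotation conflict made a chain ambiguous, the explicitly
  annotated substitution relation was preferred (see the package methods
  note).
* `golden_matches.tsv` — curated candidate/reference pairs whose printed
  substitution notations are internally consistent with the printed
  chains; pairs whose printed superscripts contradict the chains (apparent
  typos) were excluded.
* `nrps_modules.tsv` — NRPS adenylation-domain records (species, module
  position, 8-letter binding-pocket signature, two predicted token sets,
  detected amino acids). Printed typos are kept verbatim; lowercase
  predictor tokens are low-confidence by convention.
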