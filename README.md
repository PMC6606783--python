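# peptaibolkit

Identification, classification and naming of 19/20-residue **peptaibols**
from mass-spectrometric evidence.

Peptaibols are linear, membrane-active fungal peptides assembled by
non-ribosomal peptide synthetases (NRPS). The long *Trichoderma* peptaibols
handled here share one architecture: an N-terminal acetyl cap, 18–19
internal residues rich in α-aminoisobutyric acid (Aib) with a conserved
Gln at R7 and Pro at R14, and a C-terminal 1,2-amino alcohol (usually
phenylalaninol, Pheol). Because ESI-MS cannot distinguish Val from Iva or
Leu from Ile, sequences use the collapsed **Vxx/Lxx** alphabet.

The package covers the full desk workflow around such compounds:

* **`chem`** — residue registry and mass/ion arithmetic. Neutral mass
  `M = m(Ac) + Σ mᵢ + m(alcohol)`, adducts `[M+Na]⁺`, `[M+2Na]²⁺`,
  `[M+H]⁺`, and the fragment series
  `bₙ = m(Ac) + Σ₁..ₙ + m(H)`, `y_k = Σ last-k units + m(H)`.
  Printed forms are *floored* monoisotopic values (half-integer flooring
  for doubly charged ions) — the conventions that reproduce published
  compound tables cell for cell.
* **`reader`** — de novo sequence reading: R1–R13 from the full-scan b-ion
  ladder (b₇ is never observed at the stable Gln–Aib bond; a composite
  213.111 Da step assigns R7/R8), R14–R20 from the MS² spectrum of the y₇
  fragment, then assembly with mass closure against the precursor. A
  composite step arriving one position early marks the R6 vacancy of a
  19-residue chain.
* **`catalog`** — comparison against a reference catalogue: identity /
  positional-isomer / substitution reports in the field's notation
  (`[Lxx]^12 → [Vxx]^12`), single-gap alignment for 19-mers, and a
  known-vs-new verdict.
* **`naming`** — group assignment (A: Lxx at R12; B: Aib/Ala at R12;
  C: 19-residue brevicelsins) and nomenclature by elution order with
  abundance-ordered variant letters.
* **`cluster`** — complete-linkage clustering of strain × compound
  production profiles on Euclidean column distances, with Newick export.
* **`nrps`** — NRPS adenylation-domain binding-pocket signatures and
  prediction/observation agreement scoring.
* **`simulate`** — seeded synthetic spectra and block-structured strain
  profiles, so every stage is testable without instrument data.

Compound tables (groups A, B, C), a reference catalogue and the NRPS module
records ship as packaged fixtures.

## Worked example

Masses and diagnostic ions of paracelsin B:

```sh
$ peptaibolkit mass Ac-Aib-Ala-Aib-Ala-Aib-Ala-Gln-Aib-Lxx-Aib-Gly-Aib-Aib-Pro-Vxx-Aib-Aib-Gln-Gln-Pheol
{"M_exact": 1922.09888, "M": 1922, "M+Na": 1945, "M+2Na": 984.0,
 "M+H_exact": 1923.10616, "b13": 1149, "y7": 774, "y7_1dp": 774.4}
```

`M` 1922 is the floored monoisotopic neutral mass, `M+Na`/`M+2Na` the
printed adduct values, `b13` the diagnostic N-terminal fragment through the
residue preceding Pro, and `y7`/`y7_1dp` the C-terminal fragment used for
quantification and MS² selection.

Simulate that compound's spectra and read the sequence back:

```sh
$ peptaibolkit simulate Ac-Aib-...-Pheol --seed 7 -o demo
wrote demo_full.mgf (15 peaks) and demo_y7ms2.mgf (6 peaks)
$ peptaibolkit annotate demo_full.mgf demo_y7ms2.mgf --precursor 1945.09
{
 "assignments": {"R1": "Aib", "R2": "Ala", ..., "R20": "Pheol"},
 "provenance": {"R7": "composite Gln-Aib step (b ion at R7 absent)", ...},
 "closure_residual": 0.0041, "complete": true, ...
}
```

The call is complete: all twenty labels are assigned, R7/R8 were crossed
via the composite step, and the computed mass closes on the `[M+Na]⁺`
precursor within 2× tolerance.

Relate two compounds in the printed notation:

```sh
$ peptaibolkit compare "Paracelsin A" "Paracelsin B"
{... "distance": 1, "notation": "[Lxx]^9 → [Vxx]^9"}
```

Other subcommands: `ions`, `classify` (novelty against the catalogue),
`name` (group + elution-order nomenclature), `cluster` (strain profiles →
Newick), `nrps-agree`, and `run` (the whole pipeline from a YAML config).

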