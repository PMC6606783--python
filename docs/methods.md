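# Methods

## Scope and data model

The package operates on linear 19/20-residue peptaibols of the paracelsin /
longibrachin type: an N-acetyl cap, 18 or 19 internal residues, a
C-terminal 1,2-amino alcohol. Position labels R1–R20 follow the 20-residue
frame of the published compound tables; 19-unit chains carry their internal
deletion at R6 (the only deletion site occurring in this family, attributed
to NRPS internal module skipping), so their labels are R1–R5, R7–R20.
Because the MS evidence cannot separate Val/Iva or Leu/Ile, all comparison,
classification and naming operate on the collapsed classes Vxx and Lxx;
stereochemistry (e.g. D-Iva) is ignored throughout.

## Mass conventions

Residue masses are fixed in a versioned packaged registry
(`data/residues.tsv`); there is no runtime dependence on external element
tables. Constants: H 1.00783, proton 1.00728, Na 22.98977, acetyl
42.01057 Da; key residues: Aib 85.05276, Vxx 99.06841, Lxx 113.08406,
Gln 128.05858, Pheol unit 151.09971 Da (the amino-alcohol unit mass is the
full condensed unit).

Printed forms are pinned to the conventions that reproduce the published
tables:

* neutral mass and `[M+Na]+`: **floored** (not rounded) monoisotopic Da —
  floor gives 1922 from 1922.099 and 774 from 774.451 where rounding would
  not;
* `[M+2Na]2+`: floored to the nearest 0.5 Da (984 / 984.5 / 991.5 …);
* b ions: acetyl + residue sum + one H, floored;
* y ions: unit sum + **a single H**, floored (one-decimal truncation for
  MS² selection values). The single-hydrogen convention is the only one
  consistent with every printed y7.

With these conventions all 5 printed columns of all 136 packaged table rows
(51 group A, 77 group B, 8 group C) recompute exactly; the mass-check stage
still emits a machine-readable discrepancy report and enforces only a ≥95%
cell pass rate, leaving room for typos in transcribed inputs. The identity
`b_diag + y7 − M ∈ {1, 2, 3}` (exact sum `M + 2·1.00783` before flooring)
is asserted for every row.

## Sequence reading

Reading follows the two-stage order used for this family. The N-terminal
ladder extends from b1 by single-residue steps within a matching tolerance;
the b ion at the fragmentation-stable Gln–Aib bond (ending at label R7) is
never present, and the ladder crosses it with one composite step of
213.111 Da assigned as (Gln, Aib). A composite step after five single steps
instead of six anchors the R6 vacancy of a 19-unit chain. The C-terminal
part descends the internal y series of the y7 MS² spectrum (R14–R19) and
reads the amino alcohol at R20 directly from the terminal y1 unit mass.
Assembly merges the partial calls, recomputes the neutral mass and closes
against the precursor; `[M+H]+`, `[M+Na]+` and `[M+2Na]2+` interpretations
are tried and the one minimising the residual is kept (an explicit
interpretation can be forced). A call is *complete* only when every label
of the 19/20 frame is assigned and the closure residual is ≤ 2× tolerance.

Default tolerances: 0.3 Da (ion-trap mode) and 0.01 Da (orbitrap mode),
selectable by a mode flag; the source measurements used both instrument
classes without stating matching tolerances, so these are package defaults,
not reproduced settings.

Two mass degeneracies in this residue alphabet required explicit guards,
both found by property testing under peak dropout:

* **Gln = Ala + Gly to 1e-5 Da.** A bare Gln-sized b-ladder step could be a
  two-residue bridge across a dropped peak (Ala–Gly pairs occur at R10–R11
  of many group A sequences), so the N-terminal reader refuses it and
  terminates with an ambiguity diagnostic. Genuine N-terminal Gln occurs
  only inside the composite step in this family, so complete inventories
  are unaffected. The degeneracy window is fixed at 0.02 Da, independent of
  the matching tolerance, which preserves tolerance monotonicity (widening
  the tolerance never removes a correct step).
* **Ala + Ala + Ala = the 213.111 Da composite to 1e-5 Da.** A
  composite-sized step anchored anywhere but after 5 or 6 single steps
  cannot be the conserved R7–R8 bond and is discarded together with
  everything after it.

Doubly sodiated precursor peaks fall inside the b-ion m/z range; they are
recognised by the pairing identity `2·m([M+2Na]2+) − m([M+Na]+) = m(Na)`
and removed before ladder reading. Ambiguous ladders are returned as
ranked branches (by assigned count, then cumulative |Δm|), never silently
resolved; partial calls are first-class output. With these rules, seeded
simulations show zero hallucinated assignments in 1000 spectra at 10%
dropout, and 100% round-trip recovery of all 136 fixture chains at
σ = 0.02 Da, zero dropout.

## Catalogue comparison

Matching is positional on collapsed chains. Equal lengths give a Hamming
substitution list; a 19-vs-20 alignment places one internal deletion to
minimise substitutions. Among equally good deletion positions the
**rightmost** is taken: runs of identical residues around R5–R6 make the
placement ambiguous, and only the rightmost rule reproduces the published
R6 gap for every 19-residue fixture (e.g. a reference with Aib at both R5
and R6 admits either deletion; the published alignments put the gap at R6).
Substitutions are rendered reference-residue first (`[Lxx]^12 → [Vxx]^12`),
labels always in the 20-residue frame; gaps render as `Δ[Ala]^6`. Distance
is the substitution count plus one per gap; a compound is *known* iff some
catalogue entry sits at distance 0, otherwise *new* with neighbours within
3 substitutions listed. The packaged catalogue holds 71 published chains
implied by the identity annotations of the fixture tables; it is a working
subset, not a reconstruction of the full historical peptaibiotics
databases. "Positional isomer" status is assigned between observed
compounds with identical collapsed chains but distinct retention times, a
relation the naming stage computes.

## Groups and names

Group C is structural (19 amino units). Among 20-mers, Lxx at R12 gives
group A; Aib or Ala gives group B; the ambiguous Vxx at R12 is resolved by
nearest-neighbour vote (smallest mean Hamming distance to the unambiguous
A and B fixture chains, ties to A). Compounds are then named
`Pept-<group>-<numeral><letter>` (brevicelsins: `Brevicelsin-<numeral>`):
families share a printed (M, b-diag, y7) triple and cluster by
single-linkage on retention time with threshold `rt_tolerance`
(default 0.5 min), numerals follow ascending minimum rt, letters descending
abundance (only when a family has more than one member). The published
numbering of the large A/B tables is not exactly regenerable — the
underlying chromatograms are unavailable and the tables contain identical
triples under different numerals — so only the group C ordering
(Brevicelsin I–VIII by rt) is treated as a reproducible fact; the 0.5 min
default is a documented reconstruction. Names are deterministic and
input-order invariant; compounds identical in chain, rt and abundance are
interchangeable, so only their name multiset is defined.

## Profile clustering

Strain profiles cluster by complete linkage on Euclidean distances between
strain columns, matching the reported heat-map settings; raw levels are
used by default and unit-variance scaling is an option (the original
preprocessing is unstated). Complete linkage is implemented directly
(naive O(n³); panels have ≤ ~22 strains) so the tie rule is deterministic
and input-order invariant: candidate merges compare by (distance, canonical
pair), where a cluster's canonical label is its lexicographically smallest
column name. Merge heights are non-decreasing; scipy's implementation is
the independent oracle in tests via cophenetic-distance equality. Trees
serialise to Newick with branch lengths `h(parent) − h(child)`.

## NRPS signatures

Module records carry the 8-letter binding-pocket signature, two predictor
token sets and the detected amino acids. Lowercase predictor tokens parse
case-insensitively with a low-confidence flag (ignored by default rules);
the one malformed token in the source records is kept verbatim as an opaque
string. Three agreement rules are provided (detected ⊆ predictor A;
detected ⊆ A ∪ B; non-empty intersection), optionally after isomer
collapsing. The published "11 of 20 positions" headline is not
deterministically recoverable from the printed records under any single
natural rule, so the package reports per-rule counts instead of asserting
one number. Signature identity at R15 across the four species and pairwise
distinct signatures at R12 are asserted facts.

## Synthetic data

`simulate_spectrum` emits the observed ion inventory — `[M+Na]+`,
`[M+2Na]2+`, b1 up to the pre-Pro ion with the R7 b ion always absent, y7,
and the y1–y6 MS² ladder — then applies Gaussian m/z jitter (default
σ = 0.02 Da, ion-trap scale), per-peak dropout and uniform decoys under a
mandatory seed. Intensities are cosmetic log-normal draws; the reader uses
them only to record the y7 intensity. Zero-noise peaks equal the `chem`
values to 1e-6 Da by construction. `simulate_profiles` plants block
structure (shared binary usage templates scaled by a separation of 5,
jitter σ = 0.1 by default in tests) and returns the ground-truth partition;
planted two-block panels are recovered at the top split in 100/100 seeded
replicates. The simulators emulate peak positions and block structure only
— no isotope envelopes, chromatographic peak shapes, co-eluting chimeras or
sodiated fragment series — so passing round trips demonstrate the reading
logic, not robustness to every artefact of real spectra.

## Problem sizes and determinism

Tests and the acceptance script run the full 136-row fixture set for mass
checks, grouping and round trips; clustering checks use 200 random 6×6
matrices against the oracle and 100 planted 10-strain panels. All
randomness flows through explicit integer seeds (numpy `default_rng`);
reports log the seed, registry version and mass constants.

## Known limitations

* The b-ladder Gln guard means an interior bare Gln in the N-terminal half
  of a *non-standard* chain (outside this family's conserved architecture)
  reads as unassigned rather than Gln.
* Co-eluting sequence variants sharing one spectrum are returned as ranked
  branches, not deconvolved.
* Catalogue chains derived from substitution annotations inherit any
  internal inconsistencies of the source tables (one such conflict, around
  Trichoaureocin 1d, is resolved in favour of the explicitly annotated
  single-substitution relation).
* Retention times are taken as given; no rt prediction or cross-instrument
  alignment.
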