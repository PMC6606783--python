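"""Comparison of candidate sequences against a reference catalogue.

Matching operates on the collapsed Vxx/Lxx alphabet throughout: catalogues
recorded with exact isomers (Leu vs Ile, Val vs Iva) are normalised on load,
because the MS evidence behind a candidate cannot distinguish them.

A candidate relates to a reference as

* ``identical`` — same collapsed chain (distance 0);
* ``variant`` — one or more positional substitutions, rendered in the
  field's notation ``[Lxx]^12 → [Vxx]^12`` (reference residue on the left),
  plus optionally a single internal deletion (the 19-vs-20 gap, rendered
  ``Δ[Ala]^6``);
* ``positional_isomer`` — assigned between two *observed* compounds with
  identical collapsed chains but distinct retention times; this status is
  set by the naming stage, not by ``compare`` itself.

For a 19-unit candidate against a 20-unit reference the deletion is placed
to minimise substitutions; among equally good placements the rightmost is
taken, which reproduces the published R6 gap for every brevicelsin (runs of
identical residues around R5-R6 would otherwise pull the gap left).
Substitution labels are always reported in the 20-residue frame.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from importlib import resources

from .chem import PeptaibolSequence, ResidueRegistry, default_registry

__all__ = ["ReferenceEntry", "MatchReport", "load_catalog", "collapse",
           "compare", "classify_novelty", "render_notation", "parse_notation"]

ARROW = "→"
DELTA = "Δ"


@dataclass(frozen=True)
class ReferenceEntry:
    name: str
    chain: PeptaibolSequence
    citation: str = ""


@dataclass
class MatchReport:
    """Relation of a candidate chain to one reference chain."""

    candidate: str
    reference: str
    status: str  # identical | positional_isomer | variant
    substitutions: list[tuple[int, str, str]] = field(default_factory=list)
    gap_label: int | None = None
    gap_residue: str | None = None
    distance: int = 0

    @property
    def notation(self) -> str:
        return render_notation(self.substitutions, self.gap_label,
                               self.gap_residue)

    def to_dict(self) -> dict:
        return {
            "candidate": self.candidate,
            "reference": self.reference,
            "status": self.status,
            "substitutions": [
                {"label": f"R{i}", "from": a, "to": b}
                for i, a, b in self.substitutions],
            "gap": f"R{self.gap_label}" if self.gap_label else None,
            "distance": self.distance,
            "notation": self.notation,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), ensure_ascii=False, **kw)


def render_notation(substitutions, gap_label=None, gap_residue=None) -> str:
    """Paper-style text notation, ascending by label; the gap appears at its
    label position as a deletion mark."""
    items = [(lab, f"[{a}]^{lab} {ARROW} [{b}]^{lab}")
             for lab, a, b in substitutions]
    if gap_label is not None:
        items.append((gap_label, f"{DELTA}[{gap_residue}]^{gap_label}"))
    return "; ".join(s for _, s in sorted(items))


def parse_notation(text: str):
    """Inverse of render_notation (round-trip support for reports)."""
    subs, gap = [], None
    for part in [p.strip() for p in text.split(";") if p.strip()]:
        if part.startswith(DELTA):
            tok, lab = part[1:].split("]^")
            gap = (int(lab), tok.lstrip("["))
        else:
            left, right = part.split(f" {ARROW} ")
            a, i = left.split("]^")
            b, j = right.split("]^")
            if i != j:
                raise ValueError(f"label mismatch in {part!r}")
            subs.append((int(i), a.lstrip("["), b.lstrip("[")))
    return subs, gap


def collapse(seq: PeptaibolSequence) -> str:
    """Canonical hyphen-separated string in the Vxx/Lxx alphabet
    (idempotent)."""
    return seq.collapsed().to_string()


def load_catalog(path=None,
                 registry: ResidueRegistry | None = None) -> list[ReferenceEntry]:
    """Load a reference catalogue CSV (name, chain, citation).

    Defaults to the packaged catalogue assembled from compounds the source
    tables mark as identical to published peptaibols. Chains are collapsed
    on load; names must be unique.
    """
    reg = registry or default_registry()
    if path is None:
        path = resources.files("peptaibolkit.data") / "reference_catalog.csv"
    entries, seen = [], set()
    with open(str(path), newline="") as fh:
        for row in csv.DictReader(fh):
            name = row["name"].strip()
            if name in seen:
                raise ValueError(f"duplicate catalogue name {name!r}")
            seen.add(name)
            seq = PeptaibolSequence.from_string(
                row["chain"], name=name, registry=reg).collapsed()
            entries.append(ReferenceEntry(name, seq, row.get("citation", "")))
    return entries


def _labelled(seq: PeptaibolSequence) -> list[tuple[int, str]]:
    return sorted(seq.labels.items())


def compare(candidate: PeptaibolSequence,
            reference: PeptaibolSequence) -> MatchReport:
    """Positional comparison of two chains in the collapsed alphabet.

    Equal length: Hamming substitution list. 19 vs 20 units: one internal
    deletion in the longer chain, placed to minimise substitutions
    (rightmost on ties). Larger length differences are not supported.
    """
    cand = candidate.collapsed()
    ref = reference.collapsed()
    reg = cand.registry
    if reg.collapse(cand.cap) != reg.collapse(ref.cap):
        raise ValueError("candidate and reference differ in N-cap class")
    if reg.collapse(cand.alcohol) != reg.collapse(ref.alcohol):
        raise ValueError("candidate and reference differ in alcohol class")

    n_c, n_r = cand.n_amino_units, ref.n_amino_units
    name_c = candidate.name or "candidate"
    name_r = reference.name or "reference"

    if n_c == n_r:
        subs = [(lab_r, tok_r, tok_c)
                for (lab_c, tok_c), (lab_r, tok_r)
                in zip(_labelled(cand), _labelled(ref)) if tok_c != tok_r]
        dist = len(subs)
        return MatchReport(name_c, name_r,
                           "identical" if dist == 0 else "variant",
                           subs, None, None, dist)

    if abs(n_c - n_r) != 1:
        raise ValueError(
            f"cannot align chains of {n_c} and {n_r} amino units "
            "(only a single internal deletion is supported)")

    short, long_ = (cand, ref) if n_c < n_r else (ref, cand)
    short_toks = short.chain[1:]          # internal residues + alcohol
    long_lab = _labelled(long_)           # 20 labelled units
    best = None
    for d in range(len(long_lab) - 1):    # the alcohol cannot be deleted
        kept = long_lab[:d] + long_lab[d + 1:]
        subs = [(lab, tok_l, tok_s) if long_ is ref else (lab, tok_s, tok_l)
                for (lab, tok_l), tok_s in zip(kept, short_toks)
                if tok_l != tok_s]
        # rightmost deletion wins ties: >= on the substitution count
        if best is None or len(subs) <= len(best[1]):
            best = (long_lab[d][0], subs, long_lab[d][1])
    gap_lab, subs, gap_tok = best
    if long_ is not ref:
        # gap sits in the candidate's frame; substitution direction already
        # fixed above (reference residue first)
        pass
    dist = len(subs) + 1
    return MatchReport(name_c, name_r, "variant", subs, gap_lab, gap_tok, dist)


def classify_novelty(candidate: PeptaibolSequence,
                     catalogue: list[ReferenceEntry],
                     max_subs: int = 3) -> tuple[str, list[MatchReport]]:
    """Known-vs-new verdict against a catalogue.

    ``known`` iff some entry matches at distance 0; otherwise ``new`` with
    all neighbours within ``max_subs`` listed ascending by (distance, name).
    Entries whose architecture cannot be aligned (length difference > 1,
    different cap/alcohol class) are skipped.
    """
    if not catalogue:
        raise ValueError("catalogue is empty")
    reports = []
    for entry in catalogue:
        try:
            reports.append(compare(candidate, entry.chain))
        except ValueError:
            continue
    known = [r for r in reports if r.distance == 0]
    if known:
        return "known", sorted(known, key=lambda r: r.reference)
    near = [r for r in reports if r.distance <= max_subs]
    near.sort(key=lambda r: (r.distance, r.reference))
    return "new", near
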