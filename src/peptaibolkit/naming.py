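"""Group A/B/C assignment and compound nomenclature.

Groups: A and B are 20-residue peptaibols separated chiefly at R12 (Lxx in
group A, Aib — occasionally Ala — in group B); group C are the 19-residue
brevicelsins with the R6 vacancy. An R12 of Vxx occurs in both published
groups, so it is resolved by a nearest-neighbour vote against the labelled
A and B prototype chains (smallest mean Hamming distance; ties go to A).

Names follow the convention of the source tables: group letter plus a Roman
numeral family by elution order, with lowercase letters distinguishing
co-eluting variants in decreasing order of abundance ("Pept-A-IVa");
group C compounds are brevicelsins numbered by elution order. A family is a
set of compounds sharing the printed (M, b-diagnostic, y7) triple whose
retention times fall together under single-linkage at ``rt_tolerance``
(default 0.5 min — a reconstruction; the published numbering rule is not
stated and is not exactly recoverable from the tables).
"""

from __future__ import annotations

from dataclasses import dataclass

from . import chem
from .chem import PeptaibolSequence

__all__ = ["ObservedCompound", "assign_group", "assign_names", "roman",
           "parse_roman", "mark_positional_isomers"]

_ROMAN = [(100, "C"), (90, "XC"), (50, "L"), (40, "XL"), (10, "X"),
          (9, "IX"), (5, "V"), (4, "IV"), (1, "I")]


def roman(n: int) -> str:
    """Standard subtractive Roman numeral for 1 <= n <= 99."""
    if not 1 <= n <= 99:
        raise ValueError(f"Roman numeral out of supported range: {n}")
    out, rest = [], n
    for val, sym in _ROMAN:
        while rest >= val:
            out.append(sym)
            rest -= val
    return "".join(out)


def parse_roman(s: str) -> int:
    vals = {"I": 1, "V": 5, "X": 10, "L": 50, "C": 100}
    if not s or any(c not in vals for c in s):
        raise ValueError(f"not a Roman numeral: {s!r}")
    total = 0
    for i, c in enumerate(s):
        v = vals[c]
        total += -v if i + 1 < len(s) and vals[s[i + 1]] > v else v
    if roman(total) != s:
        raise ValueError(f"non-canonical Roman numeral: {s!r}")
    return total


@dataclass
class ObservedCompound:
    """A detected compound: collapsed sequence call, retention time and a
    y7-based abundance measure."""

    seq: PeptaibolSequence
    rt: float
    abundance: float = 0.0
    group: str | None = None
    name: str | None = None

    def __post_init__(self):
        if self.rt < 0:
            raise ValueError("retention time must be non-negative")
        if self.abundance < 0:
            raise ValueError("abundance must be non-negative")


def _hamming(a: PeptaibolSequence, b: PeptaibolSequence) -> int:
    la, lb = a.labels, b.labels
    return sum(la[i] != lb[i] for i in set(la) & set(lb))


def assign_group(seq: PeptaibolSequence,
                 prototypes: dict[str, list[PeptaibolSequence]] | None = None
                 ) -> str:
    """Assign group A, B or C to a collapsed chain.

    ``prototypes`` maps "A"/"B" to labelled 20-residue chains, used only for
    the nearest-neighbour vote when R12 is Vxx; defaults to the packaged
    table fixtures.
    """
    seq = seq.collapsed()
    if seq.n_amino_units == 19:
        return "C"
    r12 = seq.labels[12]
    if r12 == "Lxx":
        return "A"
    if r12 in ("Aib", "Ala"):
        return "B"
    if prototypes is None:
        prototypes = _default_prototypes()
    means = {}
    for g in ("A", "B"):
        chains = prototypes.get(g, [])
        if chains:
            means[g] = sum(_hamming(seq, c) for c in chains) / len(chains)
    if not means:
        return "A"
    best = min(means.values())
    return "A" if means.get("A", float("inf")) == best else "B"


_PROTO_CACHE: dict[str, list[PeptaibolSequence]] | None = None


def _default_prototypes() -> dict[str, list[PeptaibolSequence]]:
    global _PROTO_CACHE
    if _PROTO_CACHE is None:
        from .io import load_packaged_table
        protos: dict[str, list[PeptaibolSequence]] = {"A": [], "B": []}
        for g in ("A", "B"):
            wanted = ("Lxx",) if g == "A" else ("Aib", "Ala")
            for rec in load_packaged_table(g):
                # only unambiguous exemplars teach the vote
                if rec.seq.labels[12] in wanted:
                    protos[g].append(rec.seq.collapsed())
        _PROTO_CACHE = protos
    return _PROTO_CACHE


def _family_key(c: ObservedCompound) -> tuple:
    ms = chem.summarize(c.seq)
    return (c.group, ms.m_printed, ms.b_diag_printed, ms.y7_printed)


def _single_linkage_rt(compounds: list[ObservedCompound],
                       rt_tolerance: float) -> list[list[ObservedCompound]]:
    """Chain compounds whose successive rts differ by <= rt_tolerance."""
    ordered = sorted(compounds, key=lambda c: (c.rt, -c.abundance,
                                               c.seq.to_string()))
    families, current = [], [ordered[0]]
    for c in ordered[1:]:
        if c.rt - current[-1].rt <= rt_tolerance:
            current.append(c)
        else:
            families.append(current)
            current = [c]
    families.append(current)
    return families


def assign_names(compounds: list[ObservedCompound],
                 rt_tolerance: float = 0.5) -> list[ObservedCompound]:
    """Name grouped compounds in place and return them (order-invariant:
    permuting the input yields the same name for each compound)."""
    if rt_tolerance <= 0:
        raise ValueError("rt_tolerance must be positive")
    if not compounds:
        return []
    for c in compounds:
        if c.group is None:
            c.group = assign_group(c.seq)
    for group in sorted({c.group for c in compounds}):
        members = [c for c in compounds if c.group == group]
        by_key: dict[tuple, list[ObservedCompound]] = {}
        for c in members:
            by_key.setdefault(_family_key(c), []).append(c)
        families: list[list[ObservedCompound]] = []
        for key in sorted(by_key):
            families.extend(_single_linkage_rt(by_key[key], rt_tolerance))
        families.sort(key=lambda f: min(c.rt for c in f))
        for i, fam in enumerate(families, start=1):
            fam.sort(key=lambda c: (-c.abundance, c.rt, c.seq.to_string()))
            for j, c in enumerate(fam):
                letter = chr(ord("a") + j) if len(fam) > 1 else ""
                if group == "C":
                    c.name = f"Brevicelsin-{roman(i)}{letter}"
                else:
                    c.name = f"Pept-{group}-{roman(i)}{letter}"
    return compounds


def mark_positional_isomers(compounds: list[ObservedCompound],
                            rt_tolerance: float = 0.5) -> list[tuple[str, str]]:
    """Pairs of named compounds with identical collapsed chains but distinct
    retention times — the tables' 'positional isomer' relation (unresolved
    Val/Iva or Leu/Ile isomery)."""
    pairs = []
    by_chain: dict[str, list[ObservedCompound]] = {}
    for c in compounds:
        by_chain.setdefault(c.seq.collapsed().to_string(), []).append(c)
    for chain, group in by_chain.items():
        group.sort(key=lambda c: c.rt)
        for i, a in enumerate(group):
            for b in group[i + 1:]:
                if abs(a.rt - b.rt) > rt_tolerance:
                    pairs.append((a.name or "?", b.name or "?"))
    return pairs
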