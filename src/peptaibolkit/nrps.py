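"""NRPS adenylation-domain signatures and prediction/observation agreement.

Each record holds, for one species and one module position (1-20), the
eight-letter binding-pocket signature of the adenylation domain, the amino
acid sets predicted by two substrate predictors, and the amino acids
actually detected in the peptaibol products. Lowercase predictor tokens are
parsed case-insensitively but flagged low-confidence; unrecognised tokens
(the tables contain at least one typo) are kept verbatim as opaque strings.

The published "agreement at 11 of 20 positions" could not be reproduced
from the printed records under any single natural rule, so no one rule is
canonical here: ``agreement`` evaluates a record under an explicit rule and
``agreement_counts`` reports all of them side by side.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

from .chem import default_registry

__all__ = ["ModuleRecord", "load_modules", "agreement", "agreement_counts",
           "signature_identity", "most_variable_position"]

RULES = ("subset_of_union", "subset_of_first", "nonempty_intersection")

_SIG_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY-")


def _collapse_token(tok: str) -> str:
    reg = default_registry()
    return reg.collapse(tok) if tok in reg else tok


@dataclass(frozen=True)
class ModuleRecord:
    species: str
    position: int
    signature: str
    predicted_a: frozenset[str]
    predicted_b: frozenset[str]
    detected: frozenset[str]
    low_confidence_b: frozenset[str] = frozenset()

    def __post_init__(self):
        if not 1 <= self.position <= 20:
            raise ValueError(f"module position {self.position} out of 1..20")
        if len(self.signature) != 8 or \
                not set(self.signature) <= _SIG_ALPHABET:
            raise ValueError(
                f"signature must be 8 letters over the amino-acid alphabet "
                f"plus '-': {self.signature!r}")


def _parse_set(cell: str) -> tuple[frozenset[str], frozenset[str]]:
    """Parse a token set cell; returns (tokens, low-confidence subset)."""
    toks, low = set(), set()
    for raw in cell.split(";"):
        raw = raw.strip()
        if not raw:
            continue
        if raw.islower():
            low.add(raw.capitalize())
            toks.add(raw.capitalize())
        else:
            toks.add(raw)
    return frozenset(toks), frozenset(low)


def load_modules(path=None) -> list[ModuleRecord]:
    """Load module records from TSV (species, position, signature,
    predicted_a, predicted_b, detected; sets separated by ';')."""
    if path is None:
        path = resources.files("peptaibolkit.data") / "nrps_modules.tsv"
    records = []
    with open(str(path)) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            a, low_a = _parse_set(row["predicted_a"])
            b, low_b = _parse_set(row["predicted_b"])
            det, _ = _parse_set(row["detected"])
            records.append(ModuleRecord(
                species=row["species"], position=int(row["position"]),
                signature=row["signature"], predicted_a=a, predicted_b=b,
                detected=det, low_confidence_b=low_a | low_b))
    return records


def _maybe_collapse(tokens: frozenset[str], collapse: bool) -> frozenset[str]:
    if not collapse:
        return tokens
    return frozenset(_collapse_token(t) for t in tokens)


def agreement(record: ModuleRecord, rule: str = "subset_of_union",
              collapse_isomers: bool = False) -> bool:
    """Does the detected amino-acid set agree with the prediction?

    Rules: ``subset_of_union`` (detected within predictor A or B output),
    ``subset_of_first`` (within predictor A only), ``nonempty_intersection``
    (any shared token). With ``collapse_isomers`` the Vxx/Lxx classes are
    applied to both sides first (so e.g. predicted Iva matches detected
    Ile's sibling Val only through their shared class, not across classes).
    """
    if rule not in RULES:
        raise ValueError(f"unknown rule {rule!r}")
    det = _maybe_collapse(record.detected, collapse_isomers)
    a = _maybe_collapse(record.predicted_a, collapse_isomers)
    union = a | _maybe_collapse(record.predicted_b, collapse_isomers)
    if not det:
        return False
    if rule == "subset_of_first":
        return det <= a
    if rule == "subset_of_union":
        return det <= union
    return bool(det & union)


def agreement_counts(records: list[ModuleRecord],
                     collapse_isomers: bool = False) -> dict:
    """Per-rule counts of positions where *all* species agree, plus the
    per-species totals. JSON-serialisable."""
    by_pos: dict[int, list[ModuleRecord]] = {}
    for r in records:
        by_pos.setdefault(r.position, []).append(r)
    out: dict = {"rules": {}, "n_positions": len(by_pos)}
    for rule in RULES:
        per_species: dict[str, int] = {}
        all_species = 0
        for pos, recs in sorted(by_pos.items()):
            flags = {r.species: agreement(r, rule, collapse_isomers)
                     for r in recs}
            for sp, ok in flags.items():
                per_species[sp] = per_species.get(sp, 0) + int(ok)
            all_species += int(all(flags.values()))
        out["rules"][rule] = {"positions_all_species_agree": all_species,
                              "per_species": per_species}
    return out


def signature_identity(records: list[ModuleRecord],
                       position: int) -> dict[str, list[str]]:
    """Partition species by identical signature at a position (species
    sorted; invariant to input order)."""
    at = [r for r in records if r.position == position]
    if not at:
        raise ValueError(f"no records at position {position}")
    groups: dict[str, list[str]] = {}
    for r in at:
        groups.setdefault(r.signature, []).append(r.species)
    return {sig: sorted(sp) for sig, sp in sorted(groups.items())}


def most_variable_position(records: list[ModuleRecord]) -> int:
    """The position with the largest number of distinct signatures
    (smallest position on ties)."""
    positions = sorted({r.position for r in records})
    return max(positions,
               key=lambda p: (len(signature_identity(records, p)), -p))


def summary_json(records: list[ModuleRecord], **kw) -> str:
    data = agreement_counts(records)
    data["most_variable_position"] = most_variable_position(records)
    data["identical_positions"] = [
        p for p in sorted({r.position for r in records})
        if len(signature_identity(records, p)) == 1]
    return json.dumps(data, **kw)
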