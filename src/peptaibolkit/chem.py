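"""Residue registry and mass/ion arithmetic for 19/20-residue peptaibols.

Peptaibols handled here are linear peptides with an N-terminal acetyl cap,
18 or 19 internal residues rich in alpha-aminoisobutyric acid (Aib), and a
C-terminal 1,2-amino alcohol (most often phenylalaninol, Pheol). Because
low-resolution MS cannot distinguish Val from Iva or Leu from Ile, sequences
are expressed in the collapsed Vxx/Lxx alphabet.

Printed-value conventions
-------------------------
All "printed" forms reproduce the integer/half-integer values of published
compound tables for this family:

* neutral mass ``M`` and singly sodiated ``[M+Na]+``: floored monoisotopic Da;
* doubly sodiated ``[M+2Na]2+``: floored to the nearest 0.5 Da;
* b ions: cap + residues + H (1.00783), floored;
* y ions: sum of C-terminal unit masses + a single H, floored (or truncated
  to one decimal for MS2 selection values).

Flooring (not rounding) and the single-hydrogen y convention are pinned:
they are the only conventions that reproduce the published columns
(e.g. y7 774 from 774.451, M 1922 from 1922.099).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

__all__ = [
    "H_MASS", "PROTON_MASS", "NA_MASS", "ACETYL_MASS",
    "GLN_AIB_COMPOSITE",
    "ResidueSpec", "ResidueRegistry", "PeptaibolSequence", "MassSummary",
    "UnknownResidueError", "SequenceError",
    "floor_int", "floor_to_half", "floor_to_tenth",
    "neutral_mass", "adduct_mz", "b_ion", "y_ion", "pre_pro_b_index",
    "residue_from_delta", "summarize", "default_registry",
]

H_MASS = 1.00783        # hydrogen atom
PROTON_MASS = 1.00728   # H+ (for [M+H]+ in high-resolution mode)
NA_MASS = 22.98977      # sodium atom (as Na+ adduct, electron mass neglected)
ACETYL_MASS = 42.01057  # N-terminal acetyl cap

#: residue-mass step across the fragmentation-stable Gln-Aib bond
#: (the missing b ion): Gln 128.05858 + Aib 85.05276
GLN_AIB_COMPOSITE = 213.11134

_EPS = 1e-9  # guards float representation at floor boundaries


class UnknownResidueError(KeyError):
    """A residue token is not in the registry."""

    def __init__(self, token: str, position: int | None = None):
        self.token = token
        self.position = position
        where = f" at chain position {position}" if position is not None else ""
        super().__init__(f"unknown residue code {token!r}{where}")


class SequenceError(ValueError):
    """A chain violates the peptaibol architecture invariants."""


def floor_int(x: float) -> int:
    return math.floor(x + _EPS)


def floor_to_half(x: float) -> float:
    return math.floor(2.0 * x + _EPS) / 2.0


def floor_to_tenth(x: float) -> float:
    return math.floor(10.0 * x + _EPS) / 10.0


@dataclass(frozen=True)
class ResidueSpec:
    """One chain unit: an internal residue, the N-cap, or the amino alcohol."""

    code: str
    mono_mass: float
    unit_class: str  # internal_residue | n_cap | c_terminal_alcohol
    collapse_class: str

    def __post_init__(self):
        if self.mono_mass <= 0:
            raise ValueError(f"non-positive mass for {self.code}")


class ResidueRegistry:
    """Versioned residue-mass table.

    Masses are fixed in a packaged TSV (no runtime dependence on external
    element tables) so printed-table reproduction cannot drift.
    """

    def __init__(self, specs: Iterable[ResidueSpec], version: str = "v1"):
        self.version = version
        self._specs: dict[str, ResidueSpec] = {}
        for s in specs:
            if s.code in self._specs:
                raise ValueError(f"duplicate residue code {s.code}")
            self._specs[s.code] = s
        self._degenerate = self._find_degenerate_singles()

    @classmethod
    def from_tsv(cls, path=None) -> "ResidueRegistry":
        if path is None:
            path = resources.files("peptaibolkit.data") / "residues.tsv"
        specs, version = [], "v1"
        with open(str(path)) as fh:
            for line in fh:
                line = line.strip()
                if line.startswith("#"):
                    if "registry" in line:
                        version = line.split()[-1]
                    continue
                if not line:
                    continue
                code, mass, ucls, ccls = line.split("\t")
                specs.append(ResidueSpec(code, float(mass), ucls, ccls))
        return cls(specs, version=version)

    def __contains__(self, code: str) -> bool:
        return code in self._specs

    def spec(self, code: str, position: int | None = None) -> ResidueSpec:
        try:
            return self._specs[code]
        except KeyError:
            raise UnknownResidueError(code, position) from None

    def mass(self, code: str, position: int | None = None) -> float:
        return self.spec(code, position).mono_mass

    def collapse(self, code: str) -> str:
        return self.spec(code).collapse_class

    def codes(self, unit_class: str) -> list[str]:
        return [c for c, s in self._specs.items() if s.unit_class == unit_class]

    def internal_collapse_classes(self) -> dict[str, float]:
        """Collapsed alphabet of internal residues -> monoisotopic mass."""
        out: dict[str, float] = {}
        for s in self._specs.values():
            if s.unit_class == "internal_residue":
                out[s.collapse_class] = s.mono_mass
        return out

    def alcohol_collapse_classes(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for s in self._specs.values():
            if s.unit_class == "c_terminal_alcohol":
                out[s.collapse_class] = s.mono_mass
        return out

    def _find_degenerate_singles(self, window: float = 0.02) -> set[str]:
        """Internal residues whose mass equals a two-residue sum within
        ``window`` Da (e.g. Gln = Ala + Gly to 1e-5): a ladder step of this
        size could hide a missing intermediate peak."""
        classes = self.internal_collapse_classes()
        masses = list(classes.values())
        degen = set()
        for code, m in classes.items():
            for i, a in enumerate(masses):
                for b in masses[i:]:
                    if abs((a + b) - m) <= window:
                        degen.add(code)
        return degen

    @property
    def degenerate_single_steps(self) -> set[str]:
        return self._degenerate


_DEFAULT: ResidueRegistry | None = None


def default_registry() -> ResidueRegistry:
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = ResidueRegistry.from_tsv()
    return _DEFAULT


@dataclass
class PeptaibolSequence:
    """An ordered peptaibol chain: N-cap, 18/19 internal residues, alcohol.

    Position labels follow the 20-residue frame R1..R20 used by the compound
    tables; 19-unit chains (group C, brevicelsins) carry a vacancy at R6, the
    internal deletion produced by NRPS module skipping.
    """

    chain: list[str]
    name: str | None = None
    registry: ResidueRegistry = field(default_factory=default_registry, repr=False)

    def __post_init__(self):
        reg = self.registry
        if len(self.chain) < 3:
            raise SequenceError("chain needs a cap, internal residues and an alcohol")
        for i, tok in enumerate(self.chain):
            reg.spec(tok, position=i)
        if reg.spec(self.chain[0]).unit_class != "n_cap":
            raise SequenceError(f"chain must start with an N-cap, got {self.chain[0]!r}")
        if reg.spec(self.chain[-1]).unit_class != "c_terminal_alcohol":
            raise SequenceError(
                f"chain must end with a C-terminal alcohol, got {self.chain[-1]!r}")
        for i, tok in enumerate(self.chain[1:-1], start=1):
            if reg.spec(tok).unit_class != "internal_residue":
                raise SequenceError(f"interior unit {tok!r} at {i} is not a residue")
        if self.n_internal not in (18, 19):
            raise SequenceError(
                f"peptaibol chains carry 18 or 19 internal residues, got {self.n_internal}")

    @property
    def cap(self) -> str:
        return self.chain[0]

    @property
    def alcohol(self) -> str:
        return self.chain[-1]

    @property
    def internal(self) -> list[str]:
        return self.chain[1:-1]

    @property
    def n_internal(self) -> int:
        return len(self.chain) - 2

    @property
    def n_amino_units(self) -> int:
        """Amino units = internal residues + the alcohol (19 or 20)."""
        return self.n_internal + 1

    @property
    def has_r6_vacancy(self) -> bool:
        return self.n_amino_units == 19

    @property
    def labels(self) -> dict[int, str]:
        """Map R-label (1..20) -> token; R6 absent for 19-unit chains."""
        labs = [i for i in range(1, 21) if not (self.has_r6_vacancy and i == 6)]
        return dict(zip(labs, self.chain[1:]))

    def collapsed(self) -> "PeptaibolSequence":
        reg = self.registry
        return PeptaibolSequence(
            [reg.collapse(t) for t in self.chain], name=self.name, registry=reg)

    def to_string(self) -> str:
        return "-".join(self.chain)

    @classmethod
    def from_string(cls, s: str, name: str | None = None,
                    registry: ResidueRegistry | None = None) -> "PeptaibolSequence":
        """Parse a hyphen-separated token string like ``Ac-Aib-...-Pheol``.

        A 19-amino-unit chain is taken to carry its vacancy at R6 (the only
        deletion position occurring in this family).
        """
        reg = registry or default_registry()
        return cls([t for t in s.split("-") if t], name=name, registry=reg)

    def __len__(self) -> int:
        return len(self.chain)

    def __eq__(self, other) -> bool:
        return isinstance(other, PeptaibolSequence) and self.chain == other.chain


def neutral_mass(seq: PeptaibolSequence) -> tuple[float, int]:
    """Exact and printed (floored) monoisotopic neutral mass."""
    reg = seq.registry
    exact = reg.mass(seq.cap)
    for i, tok in enumerate(seq.internal, start=1):
        exact += reg.mass(tok, position=i)
    exact += reg.mass(seq.alcohol)
    return exact, floor_int(exact)


def adduct_mz(m_exact: float, adduct: str, charge: int = 1):
    """m/z of a pseudomolecular ion and its printed form.

    ``[M+Na]+`` prints floored; ``[M+2Na]2+`` prints floored to 0.5 Da;
    ``[M+H]+`` is reported exactly (the high-resolution convention).
    """
    if adduct == "H":
        if charge != 1:
            raise ValueError("[M+H]+ is singly charged")
        exact = m_exact + PROTON_MASS
        return exact, exact
    if adduct == "Na":
        if charge != 1:
            raise ValueError("[M+Na]+ is singly charged")
        exact = m_exact + NA_MASS
        return exact, floor_int(exact)
    if adduct == "2Na":
        if charge != 2:
            raise ValueError("[M+2Na]2+ is doubly charged")
        exact = (m_exact + 2.0 * NA_MASS) / 2.0
        return exact, floor_to_half(exact)
    raise ValueError(f"unsupported adduct {adduct!r}")


def b_ion(seq: PeptaibolSequence, n: int) -> tuple[float, int]:
    """N-terminal fragment through internal residue ``n`` (1-based chain
    position): cap + residues 1..n + H."""
    if not 1 <= n < seq.n_internal + 1:
        raise ValueError(f"b-ion index {n} out of range 1..{seq.n_internal}")
    reg = seq.registry
    exact = reg.mass(seq.cap) + sum(reg.mass(t) for t in seq.internal[:n]) + H_MASS
    return exact, floor_int(exact)


def y_ion(seq: PeptaibolSequence, k: int) -> tuple[float, int, float]:
    """C-terminal fragment of the last ``k`` units (alcohol included): sum of
    unit masses + a single H. Returns (exact, floored, one-decimal)."""
    if not 1 <= k <= seq.n_internal + 1:
        raise ValueError(f"y-ion length {k} out of range 1..{seq.n_internal + 1}")
    reg = seq.registry
    units = (seq.internal + [seq.alcohol])[-k:]
    exact = sum(reg.mass(t) for t in units) + H_MASS
    return exact, floor_int(exact), floor_to_tenth(exact)


def pre_pro_b_index(seq: PeptaibolSequence) -> int:
    """Chain index of the diagnostic b ion: the unit immediately preceding
    the single Pro (label R14). 13 for 20-unit chains, 12 for brevicelsins."""
    reg = seq.registry
    pros = [i for i, t in enumerate(seq.internal, start=1)
            if reg.collapse(t) == "Pro"]
    if len(pros) != 1:
        raise SequenceError(
            f"expected exactly one Pro in the chain, found {len(pros)}")
    if pros[0] == 1:
        raise SequenceError("Pro at the first internal position has no b ion before it")
    return pros[0] - 1


def residue_from_delta(delta: float, tolerance: float,
                       registry: ResidueRegistry | None = None):
    """Interpret a mass difference as a collapsed residue class.

    Returns a single token, an ordered ``("Gln", "Aib")`` pair for the
    composite step across the stable Gln-Aib bond, a tuple of candidates when
    several classes fall within tolerance (ambiguous), or ``None``.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    reg = registry or default_registry()
    if abs(delta - GLN_AIB_COMPOSITE) <= tolerance:
        return ("Gln", "Aib")
    hits = sorted(
        (cls for cls, m in reg.internal_collapse_classes().items()
         if abs(delta - m) <= tolerance),
        key=lambda c: abs(delta - reg.internal_collapse_classes()[c]))
    if not hits:
        return None
    if len(hits) == 1:
        return hits[0]
    return tuple(hits)


@dataclass(frozen=True)
class MassSummary:
    """The five printed diagnostic values of a compound-table row, plus the
    exact masses behind them."""

    m_exact: float
    m_printed: int
    m_na_printed: int
    m_2na_printed: float
    m_h_exact: float
    b_diag_printed: int
    y7_printed: int
    y7_1dp: float
    b_diag_index: int


def summarize(seq: PeptaibolSequence) -> MassSummary:
    m_exact, m_printed = neutral_mass(seq)
    _, na_printed = adduct_mz(m_exact, "Na", 1)
    _, na2_printed = adduct_mz(m_exact, "2Na", 2)
    mh_exact, _ = adduct_mz(m_exact, "H", 1)
    bidx = pre_pro_b_index(seq)
    _, b_printed = b_ion(seq, bidx)
    _, y7_printed, y7_1dp = y_ion(seq, 7)
    return MassSummary(m_exact, m_printed, na_printed, na2_printed, mh_exact,
                       b_printed, y7_printed, y7_1dp, bidx)
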