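"""File parsing and serialisation: compound tables, peak lists, profiles,
run configuration.

Compound tables follow the published layout — one row per compound with the
printed mass columns, retention time, the N-cap column R and residue
columns R1..R20, where a ``-`` cell at R6 marks the 19-residue vacancy.
Peak lists are accepted as MGF (via pyteomics) or two-column whitespace
text. Strain profiles are plain TSV matrices (compounds x strains).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pyteomics import mgf as _mgf

from .chem import (PeptaibolSequence, ResidueRegistry, SequenceError,
                   UnknownResidueError, default_registry)
from .reader import PeakList

__all__ = ["TableRecord", "parse_sequence_table", "write_sequence_table",
           "load_packaged_table", "read_peaklist", "write_peaklist",
           "read_profile", "write_profile", "RunConfig"]

_TABLE_COLUMNS = ["name", "M", "M_Na", "M_2Na", "b_diag", "y7", "rt", "R"] + \
    [f"R{i}" for i in range(1, 21)]


@dataclass
class TableRecord:
    """One compound-table row: identity, printed masses, rt and the chain."""

    name: str
    m_printed: int
    m_na_printed: int
    m_2na_printed: float
    b_diag_printed: int
    y7_printed: int
    rt: float
    seq: PeptaibolSequence
    abundance: float = 0.0


def parse_sequence_table(path, registry: ResidueRegistry | None = None
                         ) -> list[TableRecord]:
    """Parse a compound table TSV; malformed rows raise with the row number.

    An optional trailing ``abundance`` column is honoured.
    """
    reg = registry or default_registry()
    records = []
    with open(str(path)) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        missing = [c for c in _TABLE_COLUMNS if c not in header]
        if missing:
            raise ValueError(f"table header lacks columns: {missing}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            try:
                chain = [row["R"]] + [row[f"R{i}"] for i in range(1, 21)
                                      if row[f"R{i}"].strip() != "-"]
                vacancies = [i for i in range(1, 21)
                             if row[f"R{i}"].strip() == "-"]
                if vacancies and vacancies != [6]:
                    raise SequenceError(
                        f"vacancy only allowed at R6, found at "
                        f"{['R%d' % v for v in vacancies]}")
                seq = PeptaibolSequence(chain, name=row["name"], registry=reg)
                records.append(TableRecord(
                    name=row["name"],
                    m_printed=int(row["M"]),
                    m_na_printed=int(row["M_Na"]),
                    m_2na_printed=float(row["M_2Na"]),
                    b_diag_printed=int(row["b_diag"]),
                    y7_printed=int(row["y7"]),
                    rt=float(row["rt"]),
                    seq=seq,
                    abundance=float(row.get("abundance", 0) or 0)))
            except UnknownResidueError:
                raise
            except (SequenceError, ValueError, KeyError) as exc:
                raise ValueError(f"row {lineno}: {exc}") from exc
    return records


def write_sequence_table(records: list[TableRecord], path) -> None:
    with open(str(path), "w") as fh:
        cols = _TABLE_COLUMNS + ["abundance"]
        fh.write("\t".join(cols) + "\n")
        for r in records:
            labs = r.seq.labels
            cells = [r.name, str(r.m_printed), str(r.m_na_printed),
                     f"{r.m_2na_printed:g}", str(r.b_diag_printed),
                     str(r.y7_printed), f"{r.rt:g}", r.seq.cap]
            cells += [labs.get(i, "-") for i in range(1, 21)]
            cells.append(f"{r.abundance:g}")
            fh.write("\t".join(cells) + "\n")


def load_packaged_table(group: str,
                        registry: ResidueRegistry | None = None
                        ) -> list[TableRecord]:
    """The packaged fixture table for group 'A', 'B' or 'C'."""
    fn = {"A": "table_group_a.tsv", "B": "table_group_b.tsv",
          "C": "table_group_c.tsv"}[group.upper()]
    return parse_sequence_table(resources.files("peptaibolkit.data") / fn,
                                registry=registry)


# --- peak lists -------------------------------------------------------------

def read_peaklist(path, level: str = "full_scan",
                  precursor_mz: float | None = None,
                  tolerance: float = 0.3) -> PeakList:
    """Read MGF (first spectrum) or two-column text into a PeakList."""
    path = Path(path)
    if path.suffix.lower() == ".mgf":
        with _mgf.MGF(str(path)) as reader:
            spec = next(iter(reader), None)
        if spec is None:
            raise ValueError(f"no spectrum in {path}")
        peaks = np.column_stack([spec["m/z array"],
                                 spec["intensity array"]])
        params = spec.get("params", {})
        pep = params.get("pepmass")
        if precursor_mz is None and pep:
            precursor_mz = float(pep[0] if isinstance(pep, (tuple, list))
                                 else pep)
    else:
        data = np.loadtxt(str(path), ndmin=2)
        if data.shape[1] == 1:
            data = np.column_stack([data[:, 0], np.ones(len(data))])
        peaks = data[:, :2]
    return PeakList(peaks=peaks, level=level, precursor_mz=precursor_mz,
                    tolerance=tolerance)


def write_peaklist(pl: PeakList, path, title: str = "spectrum") -> None:
    """Write MGF (by extension) or two-column text."""
    path = Path(path)
    if path.suffix.lower() == ".mgf":
        params = {"title": title}
        if pl.precursor_mz is not None:
            params["pepmass"] = pl.precursor_mz
        spectra = [{"m/z array": pl.mz, "intensity array": pl.intensity,
                    "params": params}]
        with open(path, "w") as fh:
            _mgf.write(spectra, fh)
    else:
        np.savetxt(str(path), pl.peaks, fmt="%.6f\t%.4f")


# --- profiles ---------------------------------------------------------------

def read_profile(path) -> pd.DataFrame:
    df = pd.read_csv(str(path), sep="\t", index_col=0)
    if df.columns.duplicated().any():
        raise ValueError("duplicate strain columns in profile matrix")
    return df.fillna(0.0)


def write_profile(df: pd.DataFrame, path) -> None:
    df.to_csv(str(path), sep="\t")


# --- run configuration ------------------------------------------------------

@dataclass
class RunConfig:
    """Validated pipeline configuration (YAML key-value file)."""

    seed: int = 0
    tolerance_mode: str = "ion_trap"   # ion_trap (0.3 Da) | orbitrap (0.01 Da)
    rt_tolerance: float = 0.5
    novelty_max_subs: int = 3
    cluster_scale: bool = False
    tables: list[str] = field(default_factory=list)   # paths; empty = packaged
    catalog: str | None = None
    profile: str | None = None
    out_dir: str = "peptaibolkit_out"

    TOLERANCES = {"ion_trap": 0.3, "orbitrap": 0.01}

    def __post_init__(self):
        if self.tolerance_mode not in self.TOLERANCES:
            raise ValueError(f"unknown tolerance mode {self.tolerance_mode!r}")
        if self.rt_tolerance <= 0:
            raise ValueError("rt_tolerance must be positive")
        if self.novelty_max_subs < 0:
            raise ValueError("novelty_max_subs must be non-negative")
        self.seed = int(self.seed)

    @property
    def tolerance(self) -> float:
        return self.TOLERANCES[self.tolerance_mode]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(str(path)) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in
                               cls.__dataclass_fields__.values()}
        unknown -= {"TOLERANCES"}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = {k: v for k, v in self.__dict__.items()}
        with open(str(path), "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)
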