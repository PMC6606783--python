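"""Synthetic spectra and strain-profile matrices.

``simulate_spectrum`` emulates the ion inventory actually observed for this
peptaibol family on an ion-trap instrument: the sodiated pseudomolecular
ions ([M+Na]+ and the doubly charged [M+2Na]2+), the protonated N-terminal
b series up to the residue preceding Pro — with the b ion at the stable
Gln-Aib bond (label R7) always absent — the C-terminal y7 fragment, and a
separate MS2 ladder (y1..y6) obtained by fragmenting y7. Gaussian m/z
jitter, per-peak dropout and uniform decoy peaks are applied under a
mandatory seed. Intensities are cosmetic (log-normal): the reader is
intensity-agnostic apart from recording the y7 peak.

``simulate_profiles`` plants a block structure on a strains x compounds
production matrix, standing in for per-strain semi-quantitative profiles,
and returns the ground-truth partition for cluster-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import chem
from .chem import PeptaibolSequence
from .reader import PeakList

__all__ = ["SpectrumSimConfig", "theory_peaks", "simulate_spectrum",
           "simulate_profiles"]


@dataclass
class SpectrumSimConfig:
    """Noise model for simulated peak lists.

    noise_sigma : Gaussian m/z jitter, Da (0.02 default — ion-trap scale)
    dropout_p   : per-peak omission probability
    n_decoys    : uniform random decoy peaks added per list
    intensity_mu/sigma : log-normal intensity parameters (cosmetic)
    seed        : mandatory, every random draw derives from it
    """

    seed: int
    noise_sigma: float = 0.02
    dropout_p: float = 0.0
    n_decoys: int = 0
    intensity_mu: float = 10.0
    intensity_sigma: float = 1.0
    tolerance: float = 0.3

    def __post_init__(self):
        if not 0.0 <= self.dropout_p <= 1.0:
            raise ValueError("dropout_p must be a probability")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.n_decoys < 0:
            raise ValueError("n_decoys must be non-negative")


def theory_peaks(seq: PeptaibolSequence) -> tuple[list[float], list[float], float]:
    """Exact-theory m/z values: (full-scan list, y7-MS2 ladder, y7 value).

    Full scan: [M+Na]+, [M+2Na]2+, b1..b_prePro skipping the b ion that ends
    at the Gln of the Gln-Aib bond (label R7), and y7. MS2: y1..y6.
    """
    m_exact, _ = chem.neutral_mass(seq)
    labels = seq.labels
    # chain position of the conserved Gln at label R7 (the suppressed b ion)
    idx_by_label = {lab: i for i, lab in enumerate(sorted(labels), start=1)}
    skip_b = idx_by_label.get(7)
    pre_pro = chem.pre_pro_b_index(seq)

    full = [chem.adduct_mz(m_exact, "Na", 1)[0],
            chem.adduct_mz(m_exact, "2Na", 2)[0]]
    for n in range(1, pre_pro + 1):
        if n == skip_b:
            continue
        full.append(chem.b_ion(seq, n)[0])
    y7 = chem.y_ion(seq, 7)[0]
    full.append(y7)

    ms2 = [chem.y_ion(seq, k)[0] for k in range(1, 7)]
    return sorted(full), sorted(ms2), y7


def _materialize(mzs: list[float], rng: np.random.Generator,
                 cfg: SpectrumSimConfig) -> np.ndarray:
    mz = np.asarray(mzs, dtype=float)
    keep = rng.random(mz.size) >= cfg.dropout_p
    mz = mz[keep]
    mz = mz + rng.normal(0.0, cfg.noise_sigma, mz.size)
    inten = rng.lognormal(cfg.intensity_mu, cfg.intensity_sigma, mz.size)
    if cfg.n_decoys:
        lo, hi = 100.0, (mzs[-1] + 50.0 if mzs else 2000.0)
        dm = rng.uniform(lo, hi, cfg.n_decoys)
        di = rng.lognormal(cfg.intensity_mu - 2.0, cfg.intensity_sigma,
                           cfg.n_decoys)
        mz = np.concatenate([mz, dm])
        inten = np.concatenate([inten, di])
    order = np.argsort(mz)
    return np.column_stack([mz[order], inten[order]])


def simulate_spectrum(seq: PeptaibolSequence,
                      cfg: SpectrumSimConfig) -> tuple[PeakList, PeakList]:
    """Simulate (full-scan, y7-MS2) peak lists for one compound."""
    full_t, ms2_t, y7 = theory_peaks(seq)
    rng = np.random.default_rng(cfg.seed)
    full = PeakList(peaks=_materialize(full_t, rng, cfg), level="full_scan",
                    precursor_mz=None, tolerance=cfg.tolerance)
    ms2 = PeakList(peaks=_materialize(ms2_t, rng, cfg), level="ms2_of_y7",
                   precursor_mz=y7, tolerance=cfg.tolerance)
    return full, ms2


def simulate_profiles(n_strains: int, n_compounds: int, n_blocks: int,
                      separation: float, jitter_sigma: float,
                      seed: int) -> tuple[pd.DataFrame, np.ndarray]:
    """Block-structured production matrix (compounds x strains).

    Strains in one block share a random binary compound-usage template scaled
    by ``separation``; per-cell Gaussian jitter is added and levels are
    clipped at zero. Returns the matrix and the planted block label of each
    strain column.
    """
    if n_blocks > n_strains:
        raise ValueError("more blocks than strains")
    if n_blocks < 1 or n_compounds < 1:
        raise ValueError("invalid shape")
    rng = np.random.default_rng(seed)
    # distinct usage templates per block (resample on collision)
    while True:
        templates = rng.integers(0, 2, size=(n_blocks, n_compounds)).astype(float)
        if len({t.tobytes() for t in templates}) == n_blocks:
            break
    labels = np.sort(rng.integers(0, n_blocks, size=n_strains))
    # every block gets at least one strain
    labels[:n_blocks] = np.arange(n_blocks)
    labels = np.sort(labels)
    data = separation * templates[labels].T  # compounds x strains
    data = data + rng.normal(0.0, jitter_sigma, data.shape)
    data = np.clip(data, 0.0, None)
    df = pd.DataFrame(
        data,
        index=[f"compound_{i+1:02d}" for i in range(n_compounds)],
        columns=[f"strain_{j+1:02d}" for j in range(n_strains)])
    return df, labels
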