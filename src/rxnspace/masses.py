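"""Exact monoisotopic masses and adduct-aware MS peak annotation.

Generated candidate metabolites are matched to observed m/z peaks: for each
(molecule, adduct) pair the theoretical m/z is ``(M + shift) / |z|`` with M
the monoisotopic mass, and an assignment is made when the relative error is
within a ppm tolerance.  The summary statistics — peak coverage and the
median/mean number of candidate compounds per assigned peak — quantify how
well a candidate set explains a spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem.Descriptors import ExactMolWt

from .chem import Molecule

#: mass of a proton in Da (positive-mode shifts subtract an electron)
PROTON = 1.007276466
ELECTRON = 0.000548580


@dataclass(frozen=True)
class Peak:
    """One observed m/z feature."""

    mz: float
    intensity: float = 0.0

    def __post_init__(self):
        if self.mz <= 0:
            raise ValueError("m/z must be positive")
        if self.intensity < 0:
            raise ValueError("intensity must be non-negative")


@dataclass(frozen=True)
class Adduct:
    """An ionization adduct: name, mass shift in Da, signed charge."""

    name: str
    mass_shift: float
    charge: int
    mode: str = "negative"

    def __post_init__(self):
        if self.charge == 0:
            raise ValueError("adduct charge cannot be zero")
        expected = "positive" if self.charge > 0 else "negative"
        if self.mode != expected:
            raise ValueError(f"adduct {self.name!r}: mode inconsistent with charge sign")


#: shipped defaults; the classic singly charged species in each mode
DEFAULT_ADDUCTS = {
    "negative": [
        Adduct("[M-H]-", -PROTON, -1, "negative"),
        Adduct("[M+Cl]-", 34.968853 + ELECTRON, -1, "negative"),
    ],
    "positive": [
        Adduct("[M+H]+", PROTON, +1, "positive"),
        Adduct("[M+Na]+", 22.989218, +1, "positive"),
    ],
}


def monoisotopic_mass(mol: Molecule) -> float:
    """Sum of most-abundant-isotope atomic masses, hydrogens included."""
    rd = mol.rdmol if isinstance(mol, Molecule) else mol
    for atom in rd.GetAtoms():
        if atom.GetMass() == 0.0:
            raise ValueError(f"no isotope data for element {atom.GetSymbol()!r}")
    return ExactMolWt(rd)


def theoretical_mz(mass: float, adduct: Adduct) -> float:
    return (mass + adduct.mass_shift) / abs(adduct.charge)


@dataclass
class AnnotationTable:
    """Peak assignments plus the per-peak coverage statistics."""

    assignments: list  # (peak, molecule, adduct, ppm_error)
    n_peaks: int
    per_peak_counts: dict = field(default_factory=dict)  # peak -> n distinct compounds

    @property
    def n_assigned_peaks(self) -> int:
        return sum(1 for c in self.per_peak_counts.values() if c > 0)

    @property
    def coverage(self) -> float:
        """Fraction of peaks with at least one candidate compound."""
        return self.n_assigned_peaks / self.n_peaks if self.n_peaks else 0.0

    @property
    def median_compounds_per_peak(self) -> float:
        counts = [c for c in self.per_peak_counts.values() if c > 0]
        return float(np.median(counts)) if counts else 0.0

    @property
    def mean_compounds_per_peak(self) -> float:
        counts = [c for c in self.per_peak_counts.values() if c > 0]
        return float(np.mean(counts)) if counts else 0.0


def annotate_peaks(
    mols: Iterable[Molecule],
    peaks: Sequence[Peak],
    adducts: Optional[Sequence[Adduct]] = None,
    tol_ppm: float = 5.0,
    mode: str = "negative",
) -> AnnotationTable:
    """Assign candidate compounds to peaks within a ppm mass tolerance.

    A (molecule, adduct) pair is assigned to a peak iff
    ``|mz_obs - mz_theo| / mz_theo * 1e6 <= tol_ppm``.  Compounds are
    counted per peak at the connectivity level.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    if adducts is None:
        adducts = DEFAULT_ADDUCTS[mode]
    if not adducts:
        raise ValueError("empty adduct list")
    assignments = []
    per_peak_compounds = {p: set() for p in peaks}
    candidates = []
    for mol in mols:
        mass = monoisotopic_mass(mol)
        for ad in adducts:
            candidates.append((theoretical_mz(mass, ad), mol, ad))
    candidates.sort(key=lambda t: t[0])
    mzs = np.array([c[0] for c in candidates])
    for peak in peaks:
        # widest possible window at this tolerance
        half = peak.mz * tol_ppm * 1e-6 * 1.001
        lo = np.searchsorted(mzs, peak.mz - half, side="left")
        hi = np.searchsorted(mzs, peak.mz + half, side="right")
        for mz_theo, mol, ad in candidates[lo:hi]:
            ppm = (peak.mz - mz_theo) / mz_theo * 1e6
            if abs(ppm) <= tol_ppm:
                assignments.append((peak, mol, ad, ppm))
                per_peak_compounds[peak].add(mol.canonical_key)
    return AnnotationTable(
        assignments=assignments,
        n_peaks=len(peaks),
        per_peak_counts={p: len(s) for p, s in per_peak_compounds.items()},
    )
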