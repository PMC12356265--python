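"""De novo molecular-formula and adduct determination.

A CHON composition space is enumerated once into a mass-sorted table;
precursor assignment scans every (formula, adduct) pair whose
theoretical m/z falls inside the ppm window and keeps the smallest
absolute error among candidates with a plausible hydrogen deficiency
index.  The same table backs per-peak ion-formula decomposition for
neutral-loss analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from mfsa.chem_core import (
    ELECTRON_MASS,
    MONOISOTOPIC_MASS,
    ChemError,
    ElementCount,
    monoisotopic_mass,
    ppm_error,
    rdbe,
)

__all__ = [
    "FormulaRanges",
    "FormulaDB",
    "AdductSpec",
    "FormulaAssignment",
    "DEFAULT_ADDUCTS",
    "load_adducts",
    "adduct_mz",
    "build_formula_db",
    "assign_precursor",
    "decompose_ion",
]

_ELEMENTS = ("C", "H", "O", "N")


@dataclass(frozen=True)
class FormulaRanges:
    """Inclusive per-element bounds for CHON enumeration."""

    C: tuple[int, int] = (0, 50)
    H: tuple[int, int] = (0, 80)
    O: tuple[int, int] = (0, 20)
    N: tuple[int, int] = (0, 3)

    def __post_init__(self) -> None:
        for symbol in _ELEMENTS:
            lo, hi = getattr(self, symbol)
            if lo < 0 or lo > hi:
                raise ChemError(f"bad range for {symbol}: [{lo}, {hi}]")

    @property
    def size(self) -> int:
        out = 1
        for symbol in _ELEMENTS:
            lo, hi = getattr(self, symbol)
            out *= hi - lo + 1
        return out

    @classmethod
    def from_mapping(cls, bounds: dict) -> "FormulaRanges":
        kwargs = {k: tuple(v) for k, v in bounds.items()}
        return cls(**kwargs)


class FormulaDB:
    """Mass-sorted CHON composition table supporting window queries."""

    def __init__(self, counts: np.ndarray, masses: np.ndarray):
        order = np.argsort(masses, kind="stable")
        self.counts = counts[order]  # (n, 4) int array, columns C H O N
        self.masses = masses[order]  # neutral (uncharged) summed masses

    def __len__(self) -> int:
        return len(self.masses)

    def window(self, low: float, high: float) -> np.ndarray:
        """Row indices with neutral mass in the closed interval."""
        lo = int(np.searchsorted(self.masses, low, side="left"))
        hi = int(np.searchsorted(self.masses, high, side="right"))
        return np.arange(lo, hi)

    def formula(self, idx: int, charge: int = 0) -> ElementCount:
        c, h, o, n = (int(v) for v in self.counts[idx])
        return ElementCount({"C": c, "H": h, "O": o, "N": n}, charge=charge)

    def contains(self, f: ElementCount) -> bool:
        row = np.array([f.get(s) for s in _ELEMENTS])
        return bool((self.counts == row).all(axis=1).any())


def build_formula_db(ranges: FormulaRanges, cap: int = 5_000_000) -> FormulaDB:
    """Enumerate every CHON composition in bounds, exactly once, sorted.

    Raises when the bound product exceeds ``cap`` (suggesting narrower
    bounds) so a typo cannot exhaust memory.
    """
    if ranges.size > cap:
        raise ChemError(
            f"formula space of {ranges.size} combinations exceeds the cap of "
            f"{cap}; narrow the element bounds"
        )
    axes = [np.arange(lo, hi + 1) for lo, hi in (ranges.C, ranges.H, ranges.O, ranges.N)]
    grids = np.meshgrid(*axes, indexing="ij")
    counts = np.stack([g.ravel() for g in grids], axis=1).astype(np.int64)
    weights = np.array([MONOISOTOPIC_MASS[s] for s in _ELEMENTS])
    masses = counts @ weights
    return FormulaDB(counts, masses)


# ---------------------------------------------------------------------------
# Adducts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AdductSpec:
    """An ionization adduct: gained/lost compositions plus ion charge."""

    name: str
    polarity: str  # "pos" | "neg"
    gained: ElementCount = field(default_factory=ElementCount)
    lost: ElementCount = field(default_factory=ElementCount)
    charge: int = 1

    def __post_init__(self) -> None:
        if self.polarity not in ("pos", "neg"):
            raise ChemError(f"adduct polarity must be pos/neg, got {self.polarity!r}")
        if (self.polarity == "pos") != (self.charge > 0):
            raise ChemError(f"adduct {self.name}: polarity/charge mismatch")

    @property
    def mz_offset(self) -> float:
        """Ion m/z minus neutral mass for this adduct."""
        return (
            monoisotopic_mass(self.gained)
            - monoisotopic_mass(self.lost)
            - self.charge * ELECTRON_MASS
        )


def _ec(formula: str) -> ElementCount:
    return ElementCount.from_string(formula) if formula else ElementCount()


#: The standard ESI adducts: five positive, two negative.
DEFAULT_ADDUCTS: tuple[AdductSpec, ...] = (
    AdductSpec("[M+H]+", "pos", gained=_ec("H"), charge=1),
    AdductSpec("[M+NH4]+", "pos", gained=_ec("NH4"), charge=1),
    AdductSpec("[M+H-H2O]+", "pos", gained=_ec("H"), lost=_ec("H2O"), charge=1),
    AdductSpec("[M+CH3CN+H]+", "pos", gained=_ec("C2H4N"), charge=1),
    AdductSpec("[M+CH3NH2+H]+", "pos", gained=_ec("CH6N"), charge=1),
    AdductSpec("[M-H]-", "neg", lost=_ec("H"), charge=-1),
    AdductSpec("[M+HCOO]-", "neg", gained=_ec("CHO2"), charge=-1),
)


def load_adducts(path: str | Path | None = None) -> tuple[AdductSpec, ...]:
    """Load adduct specs from YAML; default table when no path given."""
    if path is None:
        return DEFAULT_ADDUCTS
    with Path(path).open() as fh:
        entries = yaml.safe_load(fh)
    out = []
    for e in entries:
        out.append(
            AdductSpec(
                name=e["name"],
                polarity=e["polarity"],
                gained=_ec(e.get("gained", "")),
                lost=_ec(e.get("lost", "")),
                charge=int(e.get("charge", 1 if e["polarity"] == "pos" else -1)),
            )
        )
    return tuple(out)


def adduct_mz(neutral: ElementCount, adduct: AdductSpec) -> float:
    """Theoretical m/z of a neutral molecule under an adduct."""
    if neutral.charge != 0:
        raise ChemError("adduct_mz expects a neutral composition")
    ion = neutral + adduct.gained - adduct.lost  # raises on negative counts
    if ion.is_empty():
        raise ChemError(
            f"adduct {adduct.name} leaves no atoms on {neutral.to_string()!r}"
        )
    return (
        sum(MONOISOTOPIC_MASS[s] * n for s, n in ion.items())
        - adduct.charge * ELECTRON_MASS
    )


# ---------------------------------------------------------------------------
# Precursor assignment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FormulaAssignment:
    neutral: ElementCount
    adduct: str
    theoretical_mz: float
    ppm: float
    rdbe: float


def _can_apply(counts_row: np.ndarray, lost: ElementCount) -> bool:
    for i, symbol in enumerate(_ELEMENTS):
        if counts_row[i] < lost.get(symbol):
            return False
    return True


def assign_precursor(
    precursor_mz: float,
    polarity: str,
    db: FormulaDB,
    adducts: Sequence[AdductSpec] = DEFAULT_ADDUCTS,
    tol_ppm: float = 5.0,
    rdbe_range: tuple[float, float] = (0.0, 40.0),
    max_alternatives: int = 10,
) -> tuple[FormulaAssignment | None, list[FormulaAssignment]]:
    """Best (formula, adduct) for a precursor m/z, plus ranked alternatives.

    Candidates inside the ppm window whose neutral-formula hydrogen
    deficiency index lies in ``rdbe_range`` are ranked by |ppm|; ties
    prefer RDBE closest to the range midpoint, then fewer N, then the
    lexicographically smaller formula string.
    """
    if precursor_mz <= 0:
        raise ChemError("precursor m/z must be positive")
    # slightly widened prefilter window; the exact ppm check governs
    half = precursor_mz * tol_ppm / 1e6 * 1.001 + 1e-9
    midpoint = 0.5 * (rdbe_range[0] + rdbe_range[1])
    candidates: list[FormulaAssignment] = []
    for adduct in adducts:
        if adduct.polarity != polarity:
            continue
        offset = adduct.mz_offset
        for idx in db.window(precursor_mz - half - offset, precursor_mz + half - offset):
            if not _can_apply(db.counts[idx], adduct.lost):
                continue
            neutral = db.formula(idx)
            hdi = rdbe(neutral)
            if not (rdbe_range[0] <= hdi <= rdbe_range[1]):
                continue
            theo = db.masses[idx] + offset
            if theo <= 0:  # adduct stripped the whole composition
                continue
            err = ppm_error(precursor_mz, theo)
            if abs(err) > tol_ppm:
                continue
            candidates.append(
                FormulaAssignment(neutral, adduct.name, theo, err, hdi)
            )
    # |ppm| rounded to 1e-6 so float summation-order noise cannot flip
    # the deterministic tie-break chain on exact-mass ties
    candidates.sort(
        key=lambda a: (
            round(abs(a.ppm), 6),
            abs(a.rdbe - midpoint),
            a.neutral.get("N"),
            a.neutral.to_string(),
        )
    )
    if not candidates:
        return None, []
    return candidates[0], candidates[1 : max_alternatives + 1]


def decompose_ion(
    mz: float,
    db: FormulaDB,
    charge: int = 1,
    tol_ppm: float = 5.0,
    rdbe_range: tuple[float, float] = (-0.5, 40.0),
    even_electron: bool = True,
) -> list[ElementCount]:
    """Ion compositions (charge included) matching a peak m/z.

    Results are sorted by |ppm error|.  With ``even_electron`` only
    compositions with odd H+N are considered for a +-1 ion, which is the
    parity of closed-shell even-electron ions.
    """
    if abs(charge) != 1:
        raise ChemError("only singly charged ions are supported")
    neutral_target = mz + charge * ELECTRON_MASS
    half = neutral_target * tol_ppm / 1e6 * 1.001 + 1e-9
    out: list[tuple[float, ElementCount]] = []
    for idx in db.window(neutral_target - half, neutral_target + half):
        c, h, o, n = (int(v) for v in db.counts[idx])
        if even_electron and (h + n) % 2 == 0:
            continue
        ion = db.formula(idx, charge=charge)
        hdi = rdbe(ion, neutralize=False)
        if not (rdbe_range[0] <= hdi <= rdbe_range[1]):
            continue
        err = ppm_error(neutral_target, db.masses[idx])
        if abs(err) <= tol_ppm:
            out.append((round(abs(err), 6), ion))
    out.sort(key=lambda t: (t[0], t[1].to_string()))
    return [ion for _, ion in out]
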