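"""Element-composition arithmetic and exact-mass utilities.

Everything downstream (library prediction, recognition, formula
assignment, labeling) reduces to integer element-count vectors and
monoisotopic masses, so this module is deliberately small, exact and
heavily unit-tested.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterator, Mapping

__all__ = [
    "MONOISOTOPIC_MASS",
    "ELECTRON_MASS",
    "PROTON_MASS",
    "ChemError",
    "ElementCount",
    "ElementDelta",
    "MassWindow",
    "monoisotopic_mass",
    "ppm_error",
    "tolerance_window",
    "rdbe",
]

#: Monoisotopic masses (Da), CODATA/IUPAC values to >= 6 decimals.
#: C is exactly 12 by definition of the unified atomic mass unit.
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.0078250319,
    "O": 15.9949146221,
    "N": 14.0030740052,
    "S": 31.97207069,
    "P": 30.97376151,
    "Cl": 34.96885271,
}

ELECTRON_MASS: float = 0.0005485799
#: m/z shift of protonation: mass(H) - mass(e-).
PROTON_MASS: float = MONOISOTOPIC_MASS["H"] - ELECTRON_MASS


class ChemError(ValueError):
    """Raised for invalid compositions or mass arithmetic."""


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ElementCount:
    """An element-composition vector with a signed charge.

    Counts are non-negative integers keyed by element symbol; zero
    counts are dropped so equal compositions compare equal.  ``charge``
    is 0 for neutral species and the signed ion charge otherwise.
    """

    counts: tuple[tuple[str, int], ...]
    charge: int = 0

    def __init__(self, counts: Mapping[str, int] | None = None, charge: int = 0):
        items: list[tuple[str, int]] = []
        for symbol, n in sorted((counts or {}).items()):
            if not isinstance(n, int):
                raise ChemError(f"count for {symbol} must be an integer, got {n!r}")
            if n < 0:
                raise ChemError(f"negative count for element {symbol}: {n}")
            if n > 0:
                items.append((symbol, n))
        object.__setattr__(self, "counts", tuple(items))
        object.__setattr__(self, "charge", int(charge))

    # -- constructors -------------------------------------------------

    @classmethod
    def from_string(cls, formula: str, charge: int = 0) -> "ElementCount":
        """Parse a molecular formula string such as ``"C17H17O2"``.

        An optional trailing ``+`` or ``-`` sets charge +1/-1 (explicit
        ``charge`` wins when both are given and non-zero).
        """
        text = formula.strip()
        if text.endswith("+"):
            text, implied = text[:-1], +1
        elif text.endswith("-"):
            text, implied = text[:-1], -1
        else:
            implied = 0
        counts: dict[str, int] = {}
        pos = 0
        while pos < len(text):
            m = _FORMULA_TOKEN.match(text, pos)
            if m is None or m.start() != pos:
                raise ChemError(f"cannot parse formula {formula!r} at position {pos}")
            symbol, digits = m.group(1), m.group(2)
            counts[symbol] = counts.get(symbol, 0) + (int(digits) if digits else 1)
            pos = m.end()
        return cls(counts, charge=charge if charge != 0 else implied)

    # -- accessors ----------------------------------------------------

    def get(self, symbol: str) -> int:
        return dict(self.counts).get(symbol, 0)

    @property
    def carbon(self) -> int:
        return self.get("C")

    def items(self) -> Iterator[tuple[str, int]]:
        return iter(self.counts)

    def is_empty(self) -> bool:
        return not self.counts

    # -- arithmetic ---------------------------------------------------

    def __add__(self, other: "ElementCount") -> "ElementCount":
        merged = dict(self.counts)
        for symbol, n in other.counts:
            merged[symbol] = merged.get(symbol, 0) + n
        return ElementCount(merged, charge=self.charge + other.charge)

    def __sub__(self, other: "ElementCount") -> "ElementCount":
        merged = dict(self.counts)
        for symbol, n in other.counts:
            merged[symbol] = merged.get(symbol, 0) - n
            if merged[symbol] < 0:
                raise ChemError(
                    f"subtraction gives negative {symbol} count: "
                    f"{self.to_string()} - {other.to_string()}"
                )
        return ElementCount(merged, charge=self.charge - other.charge)

    def composition_key(self) -> tuple[tuple[str, int], ...]:
        """Charge-blind composition identity (used for loss matching)."""
        return self.counts

    def to_string(self, show_charge: bool = False) -> str:
        """Hill-order formula string (C, H, then alphabetical)."""
        lookup = dict(self.counts)
        parts: list[str] = []
        for symbol in ("C", "H"):
            n = lookup.pop(symbol, 0)
            if n:
                parts.append(symbol + (str(n) if n > 1 else ""))
        for symbol in sorted(lookup):
            n = lookup[symbol]
            parts.append(symbol + (str(n) if n > 1 else ""))
        text = "".join(parts)
        if show_charge and self.charge:
            sign = "+" if self.charge > 0 else "-"
            text += sign if abs(self.charge) == 1 else f"{abs(self.charge)}{sign}"
        return text

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string(show_charge=True)


@dataclass(frozen=True)
class ElementDelta:
    """A signed per-element shift row (the mass-shift matrix entries).

    Unlike :class:`ElementCount`, entries may be negative; applying a
    delta to a composition must still yield non-negative counts.
    """

    shifts: tuple[tuple[str, int], ...]

    def __init__(self, shifts: Mapping[str, int] | None = None):
        items = tuple(
            (symbol, int(n))
            for symbol, n in sorted((shifts or {}).items())
            if int(n) != 0
        )
        object.__setattr__(self, "shifts", items)

    @classmethod
    def zero(cls) -> "ElementDelta":
        return cls({})

    def __add__(self, other: "ElementDelta") -> "ElementDelta":
        merged = dict(self.shifts)
        for symbol, n in other.shifts:
            merged[symbol] = merged.get(symbol, 0) + n
        return ElementDelta(merged)

    def apply(self, base: ElementCount) -> ElementCount:
        merged = dict(base.counts)
        for symbol, n in self.shifts:
            merged[symbol] = merged.get(symbol, 0) + n
            if merged[symbol] < 0:
                raise ChemError(
                    f"delta {dict(self.shifts)} drives {symbol} negative "
                    f"on {base.to_string()}"
                )
        return ElementCount(merged, charge=base.charge)


@dataclass(frozen=True)
class MassWindow:
    """A closed mass interval [low, high] in Da."""

    low: float
    high: float

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise ChemError(f"invalid mass window: low {self.low} > high {self.high}")

    def __contains__(self, mass: float) -> bool:
        return self.low <= mass <= self.high


def monoisotopic_mass(f: ElementCount) -> float:
    """Monoisotopic mass in Da; for |charge| = 1 the ion m/z.

    The electron mass is subtracted per unit of positive charge (and
    added per unit of negative charge), so a protonated cation's m/z is
    ``mass(neutral) + PROTON_MASS``.
    """
    if abs(f.charge) > 1:
        raise ChemError(f"charge states beyond |1| unsupported: {f.charge}")
    total = 0.0
    for symbol, n in f.counts:
        try:
            total += MONOISOTOPIC_MASS[symbol] * n
        except KeyError:
            raise ChemError(f"unknown element symbol: {symbol!r}") from None
    return total - f.charge * ELECTRON_MASS


def ppm_error(mass_exp: float, mass_theo: float) -> float:
    """Signed mass error (exp - theo) / theo * 1e6 in ppm."""
    if mass_theo <= 0:
        raise ChemError(f"theoretical mass must be positive, got {mass_theo}")
    return (mass_exp - mass_theo) / mass_theo * 1e6


def tolerance_window(mass_theo: float, tol_ppm: float) -> MassWindow:
    """Closed +-tol_ppm window around a theoretical mass."""
    if mass_theo <= 0:
        raise ChemError(f"theoretical mass must be positive, got {mass_theo}")
    if tol_ppm < 0:
        raise ChemError(f"tolerance must be non-negative, got {tol_ppm}")
    half = mass_theo * tol_ppm / 1e6
    return MassWindow(mass_theo - half, mass_theo + half)


def rdbe(f: ElementCount, neutralize: bool = True) -> float:
    """Hydrogen deficiency index C - H/2 + N/2 + 1.

    With ``neutralize`` (default), a charge of +q is treated as q extra
    protons: they are removed before evaluating, so a protonated
    molecule scores like its neutral parent.
    """
    h = f.get("H")
    if neutralize and f.charge > 0:
        h -= f.charge
    return f.get("C") - h / 2.0 + f.get("N") / 2.0 + 1.0
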