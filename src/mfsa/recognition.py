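"""Target-class recognition by diagnostic-ion formula matching.

A spectrum is a class member when at least ``min_matching_ions`` of the
library's diagnostic product-ion formulas find a peak inside the +-ppm
window, after max-min normalization over the configured m/z range and
exclusion of sub-noise-floor peaks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from mfsa.chem_core import (
    ElementCount,
    monoisotopic_mass,
    ppm_error,
    tolerance_window,
)
from mfsa.spectra_io import FeatureTable, Spectrum, normalize_range

logger = logging.getLogger(__name__)

__all__ = [
    "RecognitionRule",
    "IonMatch",
    "RecognitionHit",
    "match_diagnostic_ions",
    "recognize",
    "dehydration_dominates",
]


@dataclass(frozen=True)
class RecognitionRule:
    """Diagnostic formula set plus matching thresholds."""

    formulas: tuple[ElementCount, ...]
    tol_ppm: float = 5.0
    mz_range: tuple[float, float] = (200.0, 400.0)
    noise_threshold: float = 0.1
    min_matching_ions: int = 2

    def __post_init__(self) -> None:
        if not self.formulas:
            raise ValueError("recognition rule needs a non-empty formula set")
        if self.min_matching_ions < 1:
            raise ValueError("min_matching_ions must be >= 1")
        if not (0.0 <= self.noise_threshold <= 1.0):
            raise ValueError("noise_threshold must lie in [0, 1]")


@dataclass(frozen=True)
class IonMatch:
    formula: ElementCount
    observed_mz: float
    ppm: float
    normalized_intensity: float


@dataclass(frozen=True)
class RecognitionHit:
    feature_id: str
    matches: tuple[IonMatch, ...]

    @property
    def match_count(self) -> int:
        return len(self.matches)


def match_diagnostic_ions(s: Spectrum, rule: RecognitionRule) -> list[IonMatch]:
    """Greedy one-to-one formula <-> peak assignment ordered by |ppm|.

    Peaks below the noise floor (normalized intensity < threshold) are
    excluded; each peak satisfies at most one formula and vice versa.
    Ties at equal |ppm| prefer the more intense peak.
    """
    s = normalize_range(s, *rule.mz_range)
    peaks = [
        p
        for p in s.peaks
        if p.normalized is not None and p.normalized >= rule.noise_threshold
    ]
    pairs: list[tuple[float, float, int, int]] = []  # (|ppm|, -norm, fi, pi)
    for fi, formula in enumerate(rule.formulas):
        theo = monoisotopic_mass(formula)
        window = tolerance_window(theo, rule.tol_ppm)
        for pi, p in enumerate(peaks):
            if p.mz in window:
                pairs.append((abs(ppm_error(p.mz, theo)), -p.normalized, fi, pi))
    pairs.sort()
    used_formulas: set[int] = set()
    used_peaks: set[int] = set()
    matches: list[IonMatch] = []
    for _, _, fi, pi in pairs:
        if fi in used_formulas or pi in used_peaks:
            continue
        used_formulas.add(fi)
        used_peaks.add(pi)
        p = peaks[pi]
        theo = monoisotopic_mass(rule.formulas[fi])
        matches.append(
            IonMatch(rule.formulas[fi], p.mz, ppm_error(p.mz, theo), p.normalized)
        )
    matches.sort(key=lambda m: m.observed_mz)
    return matches


def recognize(s: Spectrum, rule: RecognitionRule) -> RecognitionHit | None:
    """A hit iff the match count reaches ``min_matching_ions``."""
    matches = match_diagnostic_ions(s, rule)
    if len(matches) >= rule.min_matching_ions:
        return RecognitionHit(s.feature_id, tuple(matches))
    logger.debug(
        "feature %s below threshold: %d matching ions", s.feature_id, len(matches)
    )
    return None


def dehydration_dominates(
    table: FeatureTable,
    mh_mz: float,
    rt: float,
    tol_ppm: float = 5.0,
    rt_tol: float = 0.1,
) -> bool | None:
    """MS1 adduct-pattern predicate: is [M+H-H2O]+ stronger than [M+H]+?

    Looks for co-eluting features (within ``rt_tol`` minutes) at the
    protonated and dehydrated m/z and compares their summed areas.
    Returns None when either feature is absent from the table.
    """
    water = 2 * 1.0078250319 + 15.9949146221
    areas = {"mh": 0.0, "dehyd": 0.0}
    found = {"mh": False, "dehyd": False}
    for _, row in table.frame.iterrows():
        if abs(row["rt"] - rt) > rt_tol:
            continue
        for key, target in (("mh", mh_mz), ("dehyd", mh_mz - water)):
            if abs(ppm_error(row["mz"], target)) <= tol_ppm:
                found[key] = True
                areas[key] += float(
                    sum(row[c] for c in table.area_columns)
                )
    if not (found["mh"] and found["dehyd"]):
        return None
    return areas["dehyd"] > areas["mh"]
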