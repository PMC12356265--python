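"""Evidence layer: neutral-loss labels, feature-ion labels, range cosine.

Neutral losses are searched only between ion pairs whose assigned
formulas carry the configured carbon counts, which suppresses the
spurious mass differences that plague all-pairs neutral-loss analysis.
Scores combine pair intensity (IA) with intensity balance (IDF).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Collection

from mfsa.chem_core import ChemError, ElementCount, ppm_error
from mfsa.formula_adduct import FormulaDB, decompose_ion
from mfsa.recognition import IonMatch, RecognitionRule, match_diagnostic_ions
from mfsa.spectra_io import Spectrum, normalize_range

__all__ = [
    "NeutralLossLabel",
    "FeatureIonLabel",
    "RangeCosine",
    "label_neutral_losses",
    "label_feature_ions",
    "range_cosine",
]


@dataclass(frozen=True)
class NeutralLossLabel:
    """A labeled ion pair whose formula difference is a target loss."""

    formula_hi: ElementCount
    formula_lo: ElementCount
    loss: ElementCount
    intensity_hi: float
    intensity_lo: float

    @property
    def ia(self) -> float:
        """Average intensity of the pair."""
        return 0.5 * (self.intensity_hi + self.intensity_lo)

    @property
    def idf(self) -> float:
        """Intensity difference factor: 1 at balance, decreasing with skew."""
        if self.ia == 0:
            return 0.0
        return 1.0 / (1.0 + abs(self.intensity_hi - self.intensity_lo) / self.ia)

    @property
    def score(self) -> float:
        return self.ia * self.idf


@dataclass(frozen=True)
class FeatureIonLabel:
    formula: ElementCount
    observed_mz: float
    ppm: float
    normalized_intensity: float
    rank: int
    score: float


@dataclass(frozen=True)
class RangeCosine:
    value: float
    matched_pairs: int
    mz_range: tuple[float, float]


def _carbon_ok(count: int, allowed: Collection[int] | None) -> bool:
    return allowed is None or count in allowed


def label_neutral_losses(
    s: Spectrum,
    mz_range: tuple[float, float],
    target_losses: Collection[ElementCount],
    db: FormulaDB,
    c_hi: Collection[int] | None = None,
    c_lo: Collection[int] | None = None,
    tol_ppm: float = 5.0,
    noise_threshold: float = 0.0,
) -> list[NeutralLossLabel]:
    """Label ion pairs whose formula difference is a target neutral loss.

    Every in-range normalized peak is assigned its best ion formula by
    bounded CHON decomposition (peaks with no formula in bounds are
    skipped).  Ordered pairs (heavier, lighter) whose carbon counts pass
    the ``c_hi``/``c_lo`` filters and whose element-wise difference
    equals a target loss get a label scored IA x IDF.
    """
    s = normalize_range(s, *mz_range)
    assigned: list[tuple[ElementCount, float]] = []
    for p in s.peaks:
        if p.normalized is None or p.normalized < noise_threshold:
            continue
        candidates = decompose_ion(p.mz, db, charge=s.charge or 1, tol_ppm=tol_ppm)
        if candidates:
            assigned.append((candidates[0], p.normalized))
    targets = {loss.composition_key(): loss for loss in target_losses}
    labels: list[NeutralLossLabel] = []
    for hi_idx, (f_hi, i_hi) in enumerate(assigned):
        if not _carbon_ok(f_hi.carbon, c_hi):
            continue
        for lo_idx, (f_lo, i_lo) in enumerate(assigned):
            if hi_idx == lo_idx or not _carbon_ok(f_lo.carbon, c_lo):
                continue
            symbols = set(dict(f_hi.counts)) | set(dict(f_lo.counts))
            try:
                delta = ElementCount(
                    {s_: f_hi.get(s_) - f_lo.get(s_) for s_ in symbols}
                )
            except ChemError:
                continue  # lighter ion not a sub-composition of the heavier
            if delta.is_empty():
                continue
            loss = targets.get(delta.composition_key())
            if loss is not None:
                labels.append(NeutralLossLabel(f_hi, f_lo, loss, i_hi, i_lo))
    labels.sort(key=lambda l: (-l.score, l.loss.to_string()))
    return labels


def label_feature_ions(
    s: Spectrum,
    mz_range: tuple[float, float],
    features: Collection[ElementCount],
    top_n: int = 5,
    tol_ppm: float = 5.0,
    noise_threshold: float = 0.0,
) -> list[FeatureIonLabel]:
    """Match characteristic ion formulas and keep the top-N by intensity.

    Score is the matched peak's normalized intensity divided by the
    maximum normalized intensity in range; ties in intensity rank by
    smaller |ppm|.
    """
    rule = RecognitionRule(
        formulas=tuple(features),
        tol_ppm=tol_ppm,
        mz_range=mz_range,
        noise_threshold=noise_threshold,
        min_matching_ions=1,
    )
    matches: list[IonMatch] = match_diagnostic_ions(s, rule)
    if not matches:
        return []
    normalized = normalize_range(s, *mz_range)
    i_max = max(
        (p.normalized for p in normalized.peaks if p.normalized is not None),
        default=0.0,
    )
    if i_max == 0:
        return []
    matches.sort(key=lambda m: (-m.normalized_intensity, abs(m.ppm)))
    return [
        FeatureIonLabel(
            formula=m.formula,
            observed_mz=m.observed_mz,
            ppm=m.ppm,
            normalized_intensity=m.normalized_intensity,
            rank=rank,
            score=m.normalized_intensity / i_max,
        )
        for rank, m in enumerate(matches[:top_n], start=1)
    ]


def range_cosine(
    q: Spectrum,
    s: Spectrum,
    mz_range: tuple[float, float],
    match_tol_ppm: float = 10.0,
) -> RangeCosine:
    """Cosine similarity over greedily matched peak pairs in a m/z window.

    Peak pairs within the ppm tolerance are matched greedily by
    closeness, each peak used at most once; the cosine is computed on
    raw in-range intensities (the quotient is invariant under uniform
    intensity scaling, so range restriction is the operative part of
    the normalization).  Empty match set scores 0.
    """
    lo, hi = mz_range
    qn = [(p.mz, p.intensity) for p in q.peaks if lo <= p.mz <= hi]
    sn = [(p.mz, p.intensity) for p in s.peaks if lo <= p.mz <= hi]
    pairs: list[tuple[float, int, int]] = []
    for qi, (qmz, _) in enumerate(qn):
        for si, (smz, _) in enumerate(sn):
            err = abs(ppm_error(qmz, smz))
            if err <= match_tol_ppm:
                pairs.append((err, qi, si))
    pairs.sort()
    used_q: set[int] = set()
    used_s: set[int] = set()
    dot = qq = ss = 0.0
    matched = 0
    for _, qi, si in pairs:
        if qi in used_q or si in used_s:
            continue
        used_q.add(qi)
        used_s.add(si)
        dot += qn[qi][1] * sn[si][1]
        qq += qn[qi][1] ** 2
        ss += sn[si][1] ** 2
        matched += 1
    if matched == 0 or qq == 0 or ss == 0:
        return RangeCosine(0.0, matched, mz_range)
    return RangeCosine(dot / math.sqrt(qq * ss), matched, mz_range)
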