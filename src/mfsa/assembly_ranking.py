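"""Rule application, candidate lookup and priority-score ranking.

Rules convert labeled evidence (feature ions, neutral losses) into
module-slot assignments; consistent assignments form candidate module
sets, each looked up in the pseudo-compound library and ranked by

    priority = sum_ions w_i * s_i + sum_losses w_j * s_j

with binary weights w and label scores s.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from mfsa.chem_core import ElementCount
from mfsa.formula_adduct import (
    DEFAULT_ADDUCTS,
    FormulaAssignment,
    FormulaRanges,
    build_formula_db,
    assign_precursor,
)
from mfsa.labeling import label_feature_ions, label_neutral_losses
from mfsa.pseudo_library import (
    NEUTRAL_LOSS,
    IonFamilyTemplate,
    PseudoCompound,
    PseudoLibrary,
)
from mfsa.recognition import RecognitionRule, recognize
from mfsa.spectra_io import FeatureTable, Spectrum

logger = logging.getLogger(__name__)

__all__ = [
    "EvidenceSpec",
    "AnnotationRule",
    "RulesConfig",
    "Candidate",
    "AnnotationReport",
    "rules_from_library",
    "load_rules_config",
    "apply_rules",
    "lookup_candidates",
    "annotate",
]


@dataclass(frozen=True)
class EvidenceSpec:
    """One required (or optional, w=0) evidence item of a rule."""

    kind: str  # "ion" | "loss"
    family: str
    formula: ElementCount  # ion formula (charged) or neutral loss formula
    weight: int = 1

    def __post_init__(self) -> None:
        if self.kind not in ("ion", "loss"):
            raise ValueError(f"evidence kind must be ion/loss, got {self.kind!r}")
        if self.weight not in (0, 1):
            raise ValueError(
                f"evidence weight must be the binary indicator 0 or 1, "
                f"got {self.weight!r}"
            )

    @property
    def key(self) -> tuple:
        return (self.kind, self.family, self.formula.composition_key())


@dataclass(frozen=True)
class AnnotationRule:
    id: str
    evidence: tuple[EvidenceSpec, ...]
    assign: tuple[tuple[int, tuple[str, ...]], ...]  # slot -> allowed submodules

    def __init__(
        self,
        id: str,
        evidence: Sequence[EvidenceSpec],
        assign: Mapping[int, str | Sequence[str]],
    ):
        if not evidence:
            raise ValueError(f"rule {id!r} has no evidence")
        norm = []
        for slot, val in sorted(assign.items()):
            ids = (val,) if isinstance(val, str) else tuple(val)
            norm.append((int(slot), ids))
        object.__setattr__(self, "id", id)
        object.__setattr__(self, "evidence", tuple(evidence))
        object.__setattr__(self, "assign", tuple(norm))


@dataclass
class RulesConfig:
    """Global thresholds plus the rule list driving annotation."""

    rules: list[AnnotationRule]
    polarity: str = "pos"
    tol_ppm: float = 5.0
    cosine_tol_ppm: float = 10.0
    normalization_range: tuple[float, float] = (200.0, 400.0)
    noise_threshold: float = 0.1
    min_matching_ions: int = 2
    top_n: int = 3
    rdbe_range: tuple[float, float] = (0.0, 40.0)
    formula_ranges: FormulaRanges = field(
        default_factory=lambda: FormulaRanges(C=(0, 40), H=(0, 60), O=(0, 15), N=(0, 0))
    )
    feature_top_n: int = 10
    require_precursor_formula: bool = False


def rules_from_library(lib: PseudoLibrary) -> list[AnnotationRule]:
    """One rule per (single-slot family, submodule) pair.

    A family whose shifts come from exactly one module slot maps each
    predicted variant formula one-to-one onto a submodule, so the rule
    set can be derived mechanically from the library definition.
    Multi-slot families are skipped (their combined shift is not
    attributable to a single submodule) and left to hand-written rules.
    """
    rules: list[AnnotationRule] = []
    ms = lib.module_set
    for t in lib.templates:
        if len(t.slots) != 1:
            if t.slots:
                logger.info("family %s spans slots %s; no auto rules", t.id, t.slots)
            continue
        slot = t.slots[0]
        kind = "loss" if t.kind == NEUTRAL_LOSS else "ion"
        for sm in ms.slots[slot - 1]:
            formula = sm.delta_for(t.id).apply(t.m0)
            rules.append(
                AnnotationRule(
                    id=f"{t.id}/{sm.id}",
                    evidence=[EvidenceSpec(kind, t.id, formula, 1)],
                    assign={slot: sm.id},
                )
            )
    return rules


def load_rules_config(path: str | Path, lib: PseudoLibrary) -> RulesConfig:
    """Load the rule-set YAML; ``rules: auto`` derives rules from the library."""
    with Path(path).open() as fh:
        doc = yaml.safe_load(fh) or {}
    known = {
        "name", "rules", "polarity", "tol_ppm", "cosine_tol_ppm",
        "normalization_range", "noise_threshold", "min_matching_ions",
        "top_n", "rdbe_range", "formula_ranges", "feature_top_n",
        "require_precursor_formula",
    }
    unknown = set(doc) - known
    if unknown:
        raise ValueError(f"unknown keys in rules config {path}: {sorted(unknown)}")
    raw_rules = doc.get("rules", "auto")
    if raw_rules == "auto":
        rules = rules_from_library(lib)
    else:
        rules = []
        for r in raw_rules:
            evidence = [
                EvidenceSpec(
                    kind=e["kind"],
                    family=e["family"],
                    formula=ElementCount.from_string(
                        str(e["formula"]),
                        charge=int(e.get("charge", 1 if e["kind"] == "ion" else 0)),
                    ),
                    weight=int(e.get("weight", 1)),
                )
                for e in r["evidence"]
            ]
            rules.append(
                AnnotationRule(id=str(r["id"]), evidence=evidence, assign=r["assign"])
            )
    cfg = RulesConfig(rules=rules)
    if "polarity" in doc:
        cfg.polarity = doc["polarity"]
    for key in (
        "tol_ppm", "cosine_tol_ppm", "noise_threshold",
    ):
        if key in doc:
            setattr(cfg, key, float(doc[key]))
    for key in ("min_matching_ions", "top_n", "feature_top_n"):
        if key in doc:
            setattr(cfg, key, int(doc[key]))
    if "require_precursor_formula" in doc:
        cfg.require_precursor_formula = bool(doc["require_precursor_formula"])
    if "normalization_range" in doc:
        cfg.normalization_range = tuple(float(v) for v in doc["normalization_range"])
    if "rdbe_range" in doc:
        cfg.rdbe_range = tuple(float(v) for v in doc["rdbe_range"])
    if "formula_ranges" in doc:
        cfg.formula_ranges = FormulaRanges.from_mapping(doc["formula_ranges"])
    return cfg


# ---------------------------------------------------------------------------
# Rule application
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MatchedEvidence:
    spec: EvidenceSpec
    score: float
    ppm: float | None = None


@dataclass
class Candidate:
    """A scored (possibly partial) module-choice hypothesis."""

    choices: dict[int, tuple[str, ...]]
    evidence: list[MatchedEvidence]
    compounds: list[PseudoCompound] = field(default_factory=list)
    tier: str = ""

    @property
    def priority_score(self) -> float:
        return sum(ev.spec.weight * ev.score for ev in self.evidence)

    @property
    def is_full(self) -> bool:
        return all(len(ids) == 1 for ids in self.choices.values())

    @property
    def mean_abs_ppm(self) -> float:
        vals = [abs(ev.ppm) for ev in self.evidence if ev.ppm is not None]
        return sum(vals) / len(vals) if vals else 0.0


Labels = dict[str, list]  # family id -> FeatureIonLabel | NeutralLossLabel list


def _find_evidence(
    spec: EvidenceSpec, ion_labels: Labels, loss_labels: Labels
) -> MatchedEvidence | None:
    key = spec.formula.composition_key()
    if spec.kind == "ion":
        best: MatchedEvidence | None = None
        for label in ion_labels.get(spec.family, []):
            if label.formula.composition_key() == key:
                cand = MatchedEvidence(spec, label.score, label.ppm)
                if best is None or cand.score > best.score:
                    best = cand
        return best
    best = None
    for label in loss_labels.get(spec.family, []):
        if label.loss.composition_key() == key:
            cand = MatchedEvidence(spec, label.score, None)
            if best is None or cand.score > best.score:
                best = cand
    return best


def apply_rules(
    ion_labels: Labels,
    loss_labels: Labels,
    rules: Sequence[AnnotationRule],
    n_slots: int,
    max_candidates: int = 64,
) -> list[Candidate]:
    """Fire rules against labels and combine assignments into candidates.

    Contradictory assignments to one slot are all kept as alternative
    options; the cartesian product across slots forms the candidate
    sets, ranked by priority score (summed over distinct evidence
    items).  Slots without any fired rule stay unconstrained.
    """
    # slot -> option (tuple of submodule ids) -> evidence by key
    options: dict[int, dict[tuple[str, ...], dict[tuple, MatchedEvidence]]] = {}
    for rule in rules:
        matched: list[MatchedEvidence] = []
        ok = True
        for spec in rule.evidence:
            found = _find_evidence(spec, ion_labels, loss_labels)
            if found is None:
                if spec.weight == 1:
                    ok = False
                    break
            else:
                matched.append(found)
        if not ok:
            continue
        for slot, ids in rule.assign:
            bucket = options.setdefault(slot, {}).setdefault(ids, {})
            for ev in matched:
                prev = bucket.get(ev.spec.key)
                if prev is None or ev.score > prev.score:
                    bucket[ev.spec.key] = ev
    if not options:
        return []
    slots = sorted(options)
    option_lists = [sorted(options[s].items()) for s in slots]
    candidates: list[Candidate] = []
    for combo in itertools.islice(
        itertools.product(*option_lists), max_candidates * 4
    ):
        merged: dict[tuple, MatchedEvidence] = {}
        choices: dict[int, tuple[str, ...]] = {}
        for slot, (ids, bucket) in zip(slots, combo):
            choices[slot] = ids
            for key, ev in bucket.items():
                prev = merged.get(key)
                if prev is None or ev.score > prev.score:
                    merged[key] = ev
        candidates.append(
            Candidate(choices=choices, evidence=sorted(
                merged.values(), key=lambda ev: ev.spec.key
            ))
        )
    candidates.sort(
        key=lambda c: (
            -c.priority_score,
            -len(c.evidence),
            c.mean_abs_ppm,
            sorted(c.choices.items()),
        )
    )
    return candidates[:max_candidates]


def lookup_candidates(
    candidate: Candidate,
    library: PseudoLibrary,
    precursor_formula: ElementCount | None = None,
) -> list[PseudoCompound]:
    """Compounds consistent with a candidate's (partial) choice vector."""
    compounds = library.by_choices(dict(candidate.choices))
    if precursor_formula is not None:
        key = precursor_formula.composition_key()
        compounds = [c for c in compounds if c.formula.composition_key() == key]
        if not compounds:
            logger.debug("precursor formula constraint excluded all candidates")
    return compounds


# ---------------------------------------------------------------------------
# End-to-end annotation
# ---------------------------------------------------------------------------


@dataclass
class AnnotationReport:
    frame: pd.DataFrame

    COLUMNS = [
        "feature_id", "rank", "status", "tier", "priority_score",
        "compound_id", "smiles", "compound_formula", "n_compounds",
        "precursor_formula", "adduct", "precursor_ppm", "rdbe",
        "match_count", "n_evidence", "evidence",
    ]

    def write_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False, float_format="%.6f")

    @property
    def recognized_ids(self) -> list[str]:
        return sorted(set(self.frame["feature_id"]))

    def top1(self, feature_id: str) -> pd.Series | None:
        rows = self.frame[
            (self.frame["feature_id"] == str(feature_id)) & (self.frame["rank"] == 1)
        ]
        return rows.iloc[0] if len(rows) else None


def _evidence_text(cand: Candidate) -> str:
    parts = [
        f"{ev.spec.kind}:{ev.spec.family}:{ev.spec.formula.to_string()}"
        f"={ev.score:.4f}"
        for ev in cand.evidence
    ]
    return ";".join(parts)


def _collect_labels(
    spectrum: Spectrum, lib: PseudoLibrary, cfg: RulesConfig, db
) -> tuple[Labels, Labels]:
    """Run the labeling layer once per family referenced by the rules."""
    ion_targets: dict[str, dict[tuple, ElementCount]] = {}
    loss_targets: dict[str, dict[tuple, ElementCount]] = {}
    for rule in cfg.rules:
        for spec in rule.evidence:
            target = ion_targets if spec.kind == "ion" else loss_targets
            target.setdefault(spec.family, {})[
                spec.formula.composition_key()
            ] = spec.formula
    ion_labels: Labels = {}
    loss_labels: Labels = {}
    for family, formulas in sorted(ion_targets.items()):
        try:
            template: IonFamilyTemplate | None = lib.template(family)
        except KeyError:
            template = None
        mz_range = (
            template.mz_range
            if template is not None and template.mz_range
            else cfg.normalization_range
        )
        ion_labels[family] = label_feature_ions(
            spectrum,
            mz_range,
            [formulas[k] for k in sorted(formulas)],
            top_n=cfg.feature_top_n,
            tol_ppm=cfg.tol_ppm,
            noise_threshold=cfg.noise_threshold,
        )
    for family, formulas in sorted(loss_targets.items()):
        try:
            template = lib.template(family)
        except KeyError:
            template = None
        mz_range = (
            template.mz_range
            if template is not None and template.mz_range
            else cfg.normalization_range
        )
        loss_labels[family] = label_neutral_losses(
            spectrum,
            mz_range,
            [formulas[k] for k in sorted(formulas)],
            db,
            c_hi=template.c_hi if template is not None else None,
            c_lo=template.c_lo if template is not None else None,
            tol_ppm=cfg.tol_ppm,
            noise_threshold=cfg.noise_threshold,
        )
    return ion_labels, loss_labels


def _tier(
    cand: Candidate,
    assignment: FormulaAssignment | None,
) -> str:
    if not cand.compounds:
        return "C"
    if cand.is_full and assignment is not None:
        key = assignment.neutral.composition_key()
        if any(c.formula.composition_key() == key for c in cand.compounds):
            return "A"
    return "B"


def annotate(
    table: FeatureTable,
    spectra: Sequence[Spectrum],
    library: PseudoLibrary,
    cfg: RulesConfig,
    adducts=DEFAULT_ADDUCTS,
) -> AnnotationReport:
    """Full pipeline: recognize -> assign -> label -> assemble -> rank.

    Per-feature failures are logged and isolated; the batch never
    aborts.  Output row order follows the feature table, so identical
    inputs yield byte-identical CSV reports.
    """
    spectra_by_id = {s.feature_id: s for s in spectra}
    recognition_rule = RecognitionRule(
        formulas=tuple(library.product_ion_formulas()),
        tol_ppm=cfg.tol_ppm,
        mz_range=cfg.normalization_range,
        noise_threshold=cfg.noise_threshold,
        min_matching_ions=cfg.min_matching_ions,
    )
    db = build_formula_db(cfg.formula_ranges)
    rows: list[dict] = []
    for feature_id in table.feature_ids:
        spectrum = spectra_by_id.get(str(feature_id))
        if spectrum is None or spectrum.is_empty:
            continue
        try:
            rows.extend(
                _annotate_one(
                    spectrum, library, cfg, recognition_rule, db, adducts
                )
            )
        except Exception:
            logger.exception("annotation failed for feature %s", feature_id)
    frame = pd.DataFrame(rows, columns=AnnotationReport.COLUMNS)
    return AnnotationReport(frame)


def _annotate_one(
    spectrum: Spectrum,
    library: PseudoLibrary,
    cfg: RulesConfig,
    recognition_rule: RecognitionRule,
    db,
    adducts,
) -> list[dict]:
    hit = recognize(spectrum, recognition_rule)
    if hit is None:
        return []
    assignment, _ = assign_precursor(
        spectrum.precursor_mz,
        cfg.polarity,
        db,
        adducts,
        tol_ppm=cfg.tol_ppm,
        rdbe_range=cfg.rdbe_range,
    )
    ion_labels, loss_labels = _collect_labels(spectrum, library, cfg, db)
    candidates = apply_rules(
        ion_labels, loss_labels, cfg.rules, library.module_set.n_slots
    )
    precursor_constraint = (
        assignment.neutral
        if (cfg.require_precursor_formula and assignment is not None)
        else None
    )
    for cand in candidates:
        cand.compounds = lookup_candidates(cand, library, precursor_constraint)
        cand.tier = _tier(cand, assignment)
    base = {
        "feature_id": spectrum.feature_id,
        "precursor_formula": assignment.neutral.to_string() if assignment else "",
        "adduct": assignment.adduct if assignment else "",
        "precursor_ppm": round(assignment.ppm, 4) if assignment else "",
        "rdbe": assignment.rdbe if assignment else "",
        "match_count": hit.match_count,
    }
    kept = [c for c in candidates if c.compounds][: cfg.top_n]
    if not kept:
        return [
            {
                **base,
                "rank": 0,
                "status": "recognized_unannotated",
                "tier": "C",
                "priority_score": 0.0,
                "compound_id": "",
                "smiles": "",
                "compound_formula": "",
                "n_compounds": 0,
                "n_evidence": 0,
                "evidence": "",
            }
        ]
    rows = []
    for rank, cand in enumerate(kept, start=1):
        top = cand.compounds[0]
        rows.append(
            {
                **base,
                "rank": rank,
                "status": "annotated",
                "tier": cand.tier,
                "priority_score": round(cand.priority_score, 6),
                "compound_id": top.compound_id,
                "smiles": top.smiles,
                "compound_formula": top.formula.to_string(),
                "n_compounds": len(cand.compounds),
                "n_evidence": len(cand.evidence),
                "evidence": _evidence_text(cand),
            }
        )
    return rows
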