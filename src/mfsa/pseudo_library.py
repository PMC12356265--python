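"""Combinatorial pseudo-compound library generation.

A target class is divided into ordered module slots; each slot offers
submodules given as SMILES fragments whose shared atoms carry integer
atom-map labels.  Full structures are assembled by merging equal labels
into single atoms.  Each submodule also carries signed element-shift
rows per diagnostic ion family; a family's predicted formula for a
combination is the family's initial formula plus the sum of the chosen
submodules' shifts.
"""

from __future__ import annotations

import itertools
import logging
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml
from rdkit import Chem
from rdkit import RDLogger

from mfsa.chem_core import ChemError, ElementCount, ElementDelta

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

__all__ = [
    "AssemblyError",
    "LibraryError",
    "SubModule",
    "ModuleSet",
    "IonFamilyTemplate",
    "DiagnosticIon",
    "PseudoCompound",
    "PseudoLibrary",
    "predict_ion_formula",
    "assemble_structure",
    "molecular_formula",
    "enumerate_library",
    "persist_library",
    "load_library",
    "load_module_config",
]

SCHEMA_VERSION = 1

PRODUCT_ION = "product_ion"
NEUTRAL_LOSS = "neutral_loss"
INSOURCE = "insource"
_KINDS = (PRODUCT_ION, NEUTRAL_LOSS, INSOURCE)


class AssemblyError(ValueError):
    """Fragment merging failed (unmatched label, valence, parse)."""


class LibraryError(RuntimeError):
    """Library store is unreadable or incompatible."""


@dataclass(frozen=True)
class SubModule:
    """One structural variant of a module slot.

    ``smiles`` is a fragment whose attachment atoms carry atom-map
    labels; ``deltas`` maps ion-family id to the element-shift row this
    variant contributes to that family's predicted formula.
    """

    id: str
    slot: int  # 1-based module index
    smiles: str
    deltas: Mapping[str, ElementDelta] = field(default_factory=dict)
    label: str = ""

    def delta_for(self, family_id: str) -> ElementDelta:
        return self.deltas.get(family_id, ElementDelta.zero())

    def labels(self) -> set[int]:
        mol = Chem.MolFromSmiles(self.smiles)
        if mol is None:
            raise AssemblyError(f"submodule {self.id}: unparsable SMILES {self.smiles!r}")
        return {a.GetAtomMapNum() for a in mol.GetAtoms() if a.GetAtomMapNum()}


@dataclass(frozen=True)
class IonFamilyTemplate:
    """A diagnostic ion or loss family and the slots that shift it.

    ``m0`` is the initial formula: a charged composition for product
    ions, the neutral lost-fragment composition for losses.  For loss
    families ``parent_family`` names the heavier partner ion family
    ("precursor" for losses off the precursor ion) and ``mz_range`` is
    the window the labeling step should scan.
    """

    id: str
    kind: str
    m0: ElementCount
    slots: tuple[int, ...] = ()
    parent_family: str = ""
    mz_range: tuple[float, float] | None = None
    c_hi: tuple[int, ...] | None = None
    c_lo: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ChemError(f"unknown ion family kind {self.kind!r}")
        if self.kind == PRODUCT_ION and self.m0.charge == 0:
            raise ChemError(f"product-ion family {self.id}: m0 must be charged")
        if self.kind == NEUTRAL_LOSS and self.m0.charge != 0:
            raise ChemError(f"neutral-loss family {self.id}: m0 must be neutral")


@dataclass
class ModuleSet:
    """Ordered module slots, each holding >= 1 submodules."""

    name: str
    slots: list[list[SubModule]]

    def __post_init__(self) -> None:
        for i, slot in enumerate(self.slots, start=1):
            if not slot:
                raise ChemError(f"module slot {i} of {self.name!r} is empty")
            for sm in slot:
                if sm.slot != i:
                    raise ChemError(
                        f"submodule {sm.id} declares slot {sm.slot} but sits in slot {i}"
                    )
        ids = [sm.id for slot in self.slots for sm in slot]
        if len(ids) != len(set(ids)):
            raise ChemError(f"duplicate submodule ids in module set {self.name!r}")

    @property
    def n_slots(self) -> int:
        return len(self.slots)

    @property
    def slot_sizes(self) -> tuple[int, ...]:
        return tuple(len(slot) for slot in self.slots)

    def submodule(self, sm_id: str) -> SubModule:
        for slot in self.slots:
            for sm in slot:
                if sm.id == sm_id:
                    return sm
        raise KeyError(sm_id)


@dataclass(frozen=True)
class DiagnosticIon:
    family_id: str
    formula: ElementCount
    kind: str


@dataclass(frozen=True)
class PseudoCompound:
    compound_id: str
    choices: tuple[str, ...]  # submodule id per slot
    smiles: str  # canonical
    formula: ElementCount  # neutral molecular formula
    ions: tuple[DiagnosticIon, ...]

    def ion(self, family_id: str) -> DiagnosticIon:
        for di in self.ions:
            if di.family_id == family_id:
                return di
        raise KeyError(family_id)


# ---------------------------------------------------------------------------
# Prediction and assembly
# ---------------------------------------------------------------------------


def predict_ion_formula(
    template: IonFamilyTemplate, choices: Sequence[SubModule]
) -> ElementCount:
    """m0 plus the element-wise sum of the chosen submodules' shifts.

    Only submodules sitting in the template's listed slots contribute.
    The shift sum is commutative, so choice order within the listed
    slots cannot change the result.
    """
    chosen_slots = [sm.slot for sm in choices]
    for slot in template.slots:
        if slot not in chosen_slots:
            raise ChemError(
                f"family {template.id}: no choice given for slot {slot}"
            )
    total = ElementDelta.zero()
    for sm in choices:
        if sm.slot in template.slots:
            total = total + sm.delta_for(template.id)
    try:
        return total.apply(template.m0)
    except ChemError as exc:
        raise ChemError(
            f"family {template.id} with choices "
            f"{[sm.id for sm in choices]}: {exc}"
        ) from exc


def _merge_fragments(smiles_list: Sequence[str], ids: Sequence[str]) -> Chem.Mol:
    combo = Chem.RWMol()
    label_owner: dict[int, int] = {}
    label_uses: dict[int, int] = {}
    for sm_id, smi in zip(ids, smiles_list):
        frag = Chem.MolFromSmiles(smi)
        if frag is None:
            raise AssemblyError(f"submodule {sm_id}: unparsable SMILES {smi!r}")
        mapping: dict[int, int] = {}
        for atom in frag.GetAtoms():
            lbl = atom.GetAtomMapNum()
            if lbl:
                label_uses[lbl] = label_uses.get(lbl, 0) + 1
            if lbl and lbl in label_owner:
                keep = label_owner[lbl]
                if combo.GetAtomWithIdx(keep).GetAtomicNum() != atom.GetAtomicNum():
                    raise AssemblyError(
                        f"label {lbl}: element mismatch at shared atom "
                        f"(submodule {sm_id})"
                    )
                mapping[atom.GetIdx()] = keep
                continue
            new_atom = Chem.Atom(atom.GetAtomicNum())
            new_atom.SetFormalCharge(atom.GetFormalCharge())
            idx = combo.AddAtom(new_atom)
            mapping[atom.GetIdx()] = idx
            if lbl:
                label_owner[lbl] = idx
        for bond in frag.GetBonds():
            b = mapping[bond.GetBeginAtomIdx()]
            e = mapping[bond.GetEndAtomIdx()]
            if combo.GetBondBetweenAtoms(b, e) is None:
                combo.AddBond(b, e, bond.GetBondType())
    unmatched = sorted(lbl for lbl, n in label_uses.items() if n < 2)
    if unmatched:
        raise AssemblyError(f"unmatched attachment label(s): {unmatched}")
    mol = combo.GetMol()
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:
        raise AssemblyError(f"merged structure fails valence sanity: {exc}") from exc
    return mol


def assemble_structure(ms: ModuleSet, choices: Sequence[SubModule]) -> str:
    """Merge one fragment per slot into a canonical SMILES string.

    Atoms carrying the same map label across fragments become a single
    atom; a shared bond present in both fragments is added once.  Output
    is RDKit-canonical and therefore deterministic per choice vector.
    """
    if len(choices) != ms.n_slots:
        raise AssemblyError(
            f"expected {ms.n_slots} choices, got {len(choices)}"
        )
    mol = _merge_fragments([sm.smiles for sm in choices], [sm.id for sm in choices])
    return Chem.MolToSmiles(mol)


def molecular_formula(smiles: str) -> ElementCount:
    """Neutral molecular formula (implicit hydrogens included)."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise AssemblyError(f"unparsable SMILES {smiles!r}")
    counts: dict[str, int] = {}
    hydrogens = 0
    for atom in mol.GetAtoms():
        counts[atom.GetSymbol()] = counts.get(atom.GetSymbol(), 0) + 1
        hydrogens += atom.GetTotalNumHs()
    counts["H"] = counts.get("H", 0) + hydrogens
    return ElementCount(counts)


# ---------------------------------------------------------------------------
# Library
# ---------------------------------------------------------------------------


@dataclass
class PseudoLibrary:
    """A deduplicated pseudo-compound library with lookup indexes."""

    module_set: ModuleSet
    templates: list[IonFamilyTemplate]
    compounds: list[PseudoCompound]
    #: canonical SMILES -> choice vectors merged away during dedup
    duplicates: dict[str, list[tuple[str, ...]]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.compounds)

    def template(self, family_id: str) -> IonFamilyTemplate:
        for t in self.templates:
            if t.id == family_id:
                return t
        raise KeyError(family_id)

    def by_ion_formula(self, formula: ElementCount) -> list[PseudoCompound]:
        key = formula.composition_key()
        return [
            c
            for c in self.compounds
            if any(di.formula.composition_key() == key for di in c.ions)
        ]

    def by_choices(
        self, partial: Mapping[int, str | Iterable[str]]
    ) -> list[PseudoCompound]:
        """Compounds consistent with a (partial) slot -> submodule map."""
        wanted: dict[int, set[str]] = {}
        for slot, val in partial.items():
            wanted[int(slot)] = {val} if isinstance(val, str) else set(val)
        out = []
        for c in self.compounds:
            ok = all(c.choices[slot - 1] in ids for slot, ids in wanted.items())
            if ok:
                out.append(c)
        return out

    def product_ion_formulas(self) -> list[ElementCount]:
        """Distinct predicted product-ion formulas across the library."""
        seen: dict[tuple, ElementCount] = {}
        for c in self.compounds:
            for di in c.ions:
                if di.kind == PRODUCT_ION:
                    seen.setdefault(di.formula.composition_key(), di.formula)
        return [seen[k] for k in sorted(seen)]


def enumerate_library(
    ms: ModuleSet, templates: Sequence[IonFamilyTemplate]
) -> PseudoLibrary:
    """Enumerate every module combination and predict all family formulas.

    The pre-dedup count is exactly the product of slot sizes; duplicate
    canonical structures collapse to the first-seen compound with the
    losing choice vectors recorded as provenance.
    """
    compounds: list[PseudoCompound] = []
    by_smiles: dict[str, PseudoCompound] = {}
    duplicates: dict[str, list[tuple[str, ...]]] = {}
    counter = 0
    for combo in itertools.product(*ms.slots):
        counter += 1
        smiles = assemble_structure(ms, combo)
        choice_ids = tuple(sm.id for sm in combo)
        if smiles in by_smiles:
            duplicates.setdefault(smiles, []).append(choice_ids)
            logger.info("duplicate structure for choices %s", choice_ids)
            continue
        ions = tuple(
            DiagnosticIon(t.id, predict_ion_formula(t, combo), t.kind)
            for t in templates
        )
        compound = PseudoCompound(
            compound_id=f"{ms.name}-{counter:05d}",
            choices=choice_ids,
            smiles=smiles,
            formula=molecular_formula(smiles),
            ions=ions,
        )
        by_smiles[smiles] = compound
        compounds.append(compound)
    return PseudoLibrary(ms, list(templates), compounds, duplicates)


# ---------------------------------------------------------------------------
# YAML module-set definition
# ---------------------------------------------------------------------------


def _parse_delta(raw: Mapping[str, int]) -> ElementDelta:
    return ElementDelta({str(k): int(v) for k, v in raw.items()})


def load_module_config(path: str | Path) -> tuple[ModuleSet, list[IonFamilyTemplate]]:
    """Load a module-set definition file (fragments, shifts, templates)."""
    with Path(path).open() as fh:
        doc = yaml.safe_load(fh)
    slots: list[list[SubModule]] = []
    for module in doc["modules"]:
        index = int(module["index"])
        subs = [
            SubModule(
                id=str(e["id"]),
                slot=index,
                smiles=str(e["smiles"]),
                deltas={
                    fam: _parse_delta(d) for fam, d in (e.get("deltas") or {}).items()
                },
                label=str(e.get("label", "")),
            )
            for e in module["submodules"]
        ]
        slots.append(subs)
    templates = []
    for t in doc.get("templates", []):
        kind = t["kind"]
        charge = int(t.get("charge", 1 if kind == PRODUCT_ION else 0))
        templates.append(
            IonFamilyTemplate(
                id=str(t["id"]),
                kind=kind,
                m0=ElementCount.from_string(str(t["m0"]), charge=charge),
                slots=tuple(int(s) for s in t.get("slots", [])),
                parent_family=str(t.get("parent", "")),
                mz_range=tuple(t["mz_range"]) if t.get("mz_range") else None,
                c_hi=tuple(t["c_hi"]) if t.get("c_hi") else None,
                c_lo=tuple(t["c_lo"]) if t.get("c_lo") else None,
            )
        )
    return ModuleSet(str(doc["name"]), slots), templates


# ---------------------------------------------------------------------------
# SQLite persistence
# ---------------------------------------------------------------------------

_SCHEMA = """
CREATE TABLE meta (key TEXT PRIMARY KEY, value TEXT);
CREATE TABLE submodules (
    id TEXT PRIMARY KEY, slot INTEGER, smiles TEXT, label TEXT, deltas TEXT
);
CREATE TABLE templates (
    id TEXT PRIMARY KEY, kind TEXT, m0 TEXT, charge INTEGER, slots TEXT,
    parent TEXT, mz_range TEXT, c_hi TEXT, c_lo TEXT
);
CREATE TABLE compounds (
    compound_id TEXT PRIMARY KEY, choices TEXT, smiles TEXT UNIQUE, formula TEXT
);
CREATE TABLE ions (
    compound_id TEXT, family TEXT, formula TEXT, charge INTEGER, kind TEXT
);
CREATE TABLE duplicates (smiles TEXT, choices TEXT);
CREATE INDEX ions_by_formula ON ions (formula);
CREATE INDEX ions_by_compound ON ions (compound_id);
"""


def _join(values: Iterable) -> str:
    return ",".join(str(v) for v in values)


def persist_library(lib: PseudoLibrary, path: str | Path) -> None:
    """Write the library to a single-file SQLite store."""
    path = Path(path)
    if path.exists():
        path.unlink()
    con = sqlite3.connect(path)
    try:
        con.executescript(_SCHEMA)
        con.execute(
            "INSERT INTO meta VALUES ('schema_version', ?)", (str(SCHEMA_VERSION),)
        )
        con.execute("INSERT INTO meta VALUES ('name', ?)", (lib.module_set.name,))
        for slot in lib.module_set.slots:
            for sm in slot:
                deltas = {
                    fam: dict(d.shifts) for fam, d in sm.deltas.items()
                }
                con.execute(
                    "INSERT INTO submodules VALUES (?,?,?,?,?)",
                    (sm.id, sm.slot, sm.smiles, sm.label, yaml.safe_dump(deltas)),
                )
        for t in lib.templates:
            con.execute(
                "INSERT INTO templates VALUES (?,?,?,?,?,?,?,?,?)",
                (
                    t.id,
                    t.kind,
                    t.m0.to_string(),
                    t.m0.charge,
                    _join(t.slots),
                    t.parent_family,
                    _join(t.mz_range) if t.mz_range else "",
                    _join(t.c_hi) if t.c_hi else "",
                    _join(t.c_lo) if t.c_lo else "",
                ),
            )
        for c in lib.compounds:
            con.execute(
                "INSERT INTO compounds VALUES (?,?,?,?)",
                (c.compound_id, _join(c.choices), c.smiles, c.formula.to_string()),
            )
            for di in c.ions:
                con.execute(
                    "INSERT INTO ions VALUES (?,?,?,?,?)",
                    (
                        c.compound_id,
                        di.family_id,
                        di.formula.to_string(),
                        di.formula.charge,
                        di.kind,
                    ),
                )
        for smiles, losers in lib.duplicates.items():
            for choices in losers:
                con.execute(
                    "INSERT INTO duplicates VALUES (?,?)", (smiles, _join(choices))
                )
        con.commit()
    finally:
        con.close()


def load_library(path: str | Path) -> PseudoLibrary:
    """Load a persisted library; refuses mismatched or corrupt stores."""
    path = Path(path)
    if not path.exists():
        raise LibraryError(f"library file not found: {path}")
    con = sqlite3.connect(path)
    try:
        try:
            row = con.execute(
                "SELECT value FROM meta WHERE key='schema_version'"
            ).fetchone()
        except sqlite3.DatabaseError as exc:
            raise LibraryError(f"unreadable library file {path}: {exc}") from exc
        if row is None or int(row[0]) != SCHEMA_VERSION:
            found = None if row is None else row[0]
            raise LibraryError(
                f"library schema version mismatch: found {found}, "
                f"expected {SCHEMA_VERSION}"
            )
        name = con.execute("SELECT value FROM meta WHERE key='name'").fetchone()[0]
        slot_map: dict[int, list[SubModule]] = {}
        for sm_id, slot, smiles, label, deltas_text in con.execute(
            "SELECT id, slot, smiles, label, deltas FROM submodules ORDER BY rowid"
        ):
            deltas_raw = yaml.safe_load(deltas_text) or {}
            deltas = {fam: ElementDelta(d) for fam, d in deltas_raw.items()}
            slot_map.setdefault(slot, []).append(
                SubModule(sm_id, slot, smiles, deltas, label)
            )
        ms = ModuleSet(name, [slot_map[k] for k in sorted(slot_map)])
        templates = []
        for tid, kind, m0, charge, slots, parent, mz_range, c_hi, c_lo in con.execute(
            "SELECT id, kind, m0, charge, slots, parent, mz_range, c_hi, c_lo "
            "FROM templates ORDER BY rowid"
        ):
            templates.append(
                IonFamilyTemplate(
                    id=tid,
                    kind=kind,
                    m0=ElementCount.from_string(m0, charge=charge),
                    slots=tuple(int(s) for s in slots.split(",") if s),
                    parent_family=parent,
                    mz_range=(
                        tuple(float(v) for v in mz_range.split(","))
                        if mz_range
                        else None
                    ),
                    c_hi=tuple(int(v) for v in c_hi.split(",")) if c_hi else None,
                    c_lo=tuple(int(v) for v in c_lo.split(",")) if c_lo else None,
                )
            )
        ion_map: dict[str, list[DiagnosticIon]] = {}
        for cid, family, formula, charge, kind in con.execute(
            "SELECT compound_id, family, formula, charge, kind FROM ions ORDER BY rowid"
        ):
            ion_map.setdefault(cid, []).append(
                DiagnosticIon(family, ElementCount.from_string(formula, charge=charge), kind)
            )
        compounds = []
        for cid, choices, smiles, formula in con.execute(
            "SELECT compound_id, choices, smiles, formula FROM compounds ORDER BY rowid"
        ):
            compounds.append(
                PseudoCompound(
                    compound_id=cid,
                    choices=tuple(choices.split(",")),
                    smiles=smiles,
                    formula=ElementCount.from_string(formula),
                    ions=tuple(ion_map.get(cid, ())),
                )
            )
        duplicates: dict[str, list[tuple[str, ...]]] = {}
        for smiles, choices in con.execute("SELECT smiles, choices FROM duplicates"):
            duplicates.setdefault(smiles, []).append(tuple(choices.split(",")))
        return PseudoLibrary(ms, templates, compounds, duplicates)
    finally:
        con.close()
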