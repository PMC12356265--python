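import itertools
import sqlite3

import pytest
from rdkit import Chem

from mfsa.chem_core import ChemError, ElementCount, ElementDelta
from mfsa.pseudo_library import (
    AssemblyError,
    IonFamilyTemplate,
    LibraryError,
    ModuleSet,
    SubModule,
    assemble_structure,
    enumerate_library,
    load_library,
    molecular_formula,
    persist_library,
    predict_ion_formula,
)


def ec(formula, charge=0):
    return ElementCount.from_string(formula, charge=charge)


def template(m0="C17H17O2", slots=(1,), family="fam"):
    return IonFamilyTemplate(family, "product_ion", ec(m0, charge=1), slots=tuple(slots))


def sub(sid, slot, smiles="C[C:1]", family="fam", delta=None):
    deltas = {family: ElementDelta(delta or {})}
    return SubModule(sid, slot, smiles, deltas)


class TestPredictIonFormula:
    def test_identity_combination(self):
        t = template()
        choice = sub("s", 1)
        assert predict_ion_formula(t, [choice]) == ec("C17H17O2", charge=1)

    def test_single_oxygen_shift(self):
        # the 12-benzoyloxy analog's core ion: one +O submodule shift
        t = template()
        choice = sub("s", 1, delta={"O": 1})
        assert predict_ion_formula(t, [choice]) == ec("C17H17O3", charge=1)

    def test_two_shifts_add_elementwise(self):
        t = template(slots=(1, 2))
        c1 = sub("s1", 1, delta={"H": 2})
        c2 = sub("s2", 2, delta={"O": 1})
        assert predict_ion_formula(t, [c1, c2]) == ec("C17H19O3", charge=1)

    def test_order_independent(self):
        t = template(slots=(1, 2))
        c1 = sub("s1", 1, delta={"H": 2})
        c2 = sub("s2", 2, delta={"O": 1})
        assert predict_ion_formula(t, [c1, c2]) == predict_ion_formula(t, [c2, c1])

    def test_unlisted_slot_does_not_contribute(self):
        t = template(slots=(1,))
        c1 = sub("s1", 1, delta={"O": 1})
        c2 = sub("s2", 2, delta={"C": 5})
        assert predict_ion_formula(t, [c1, c2]) == ec("C17H17O3", charge=1)

    def test_negative_result_names_family(self):
        t = template(m0="C3H4O2", family="lossy")
        choice = sub("s", 1, family="lossy", delta={"O": -3})
        with pytest.raises(ChemError, match="lossy"):
            predict_ion_formula(t, [choice])

    def test_missing_slot_choice_rejected(self):
        t = template(slots=(1, 2))
        with pytest.raises(ChemError, match="slot 2"):
            predict_ion_formula(t, [sub("s", 1)])


class TestAssembleStructure:
    def test_single_shared_atom_merge(self):
        ms = ModuleSet(
            "t",
            [[SubModule("a", 1, "CC[C:1]")], [SubModule("b", 2, "[C:1]O")]],
        )
        smiles = assemble_structure(ms, [ms.slots[0][0], ms.slots[1][0]])
        mol = Chem.MolFromSmiles(smiles)
        assert mol.GetNumAtoms() == 3 + 2 - 1
        assert smiles == Chem.CanonSmiles("CCCO")

    def test_deterministic(self, toy_set_234):
        ms, _ = toy_set_234
        choices = [ms.slots[0][0], ms.slots[1][2], ms.slots[2][3]]
        assert assemble_structure(ms, choices) == assemble_structure(ms, choices)

    def test_tetracyclic_shared_edge(self):
        # two bicyclic fragments sharing a labeled two-atom ring edge
        ms = ModuleSet(
            "t",
            [
                [SubModule("ab", 1, "C1CC2CCC[C:1]2[C:2]1")],
                [SubModule("cd", 2, "[C:1]1[C:2]CCC2CCCC12")],
            ],
        )
        smiles = assemble_structure(ms, [ms.slots[0][0], ms.slots[1][0]])
        mol = Chem.MolFromSmiles(smiles)
        assert mol.GetNumAtoms() == 8 + 9 - 2
        assert mol.GetRingInfo().NumRings() == 4

    def test_unmatched_label_named(self):
        ms = ModuleSet(
            "t", [[SubModule("a", 1, "CC[C:7]")], [SubModule("b", 2, "[C:1]O[C:7]")]]
        )
        with pytest.raises(AssemblyError, match=r"\[1\]"):
            assemble_structure(ms, [ms.slots[0][0], ms.slots[1][0]])

    def test_valence_violation_detected(self):
        ms = ModuleSet(
            "t",
            [
                [SubModule("a", 1, "C[C:1](C)C")],
                [SubModule("b", 2, "C[C:1](C)C")],
            ],
        )
        with pytest.raises(AssemblyError, match="valence"):
            assemble_structure(ms, [ms.slots[0][0], ms.slots[1][0]])

    def test_element_mismatch_at_shared_atom(self):
        ms = ModuleSet(
            "t", [[SubModule("a", 1, "C[C:1]")], [SubModule("b", 2, "[N:1]C")]]
        )
        with pytest.raises(AssemblyError, match="mismatch"):
            assemble_structure(ms, [ms.slots[0][0], ms.slots[1][0]])

    def test_wrong_choice_count(self, toy_set_234):
        ms, _ = toy_set_234
        with pytest.raises(AssemblyError):
            assemble_structure(ms, [ms.slots[0][0]])


def test_molecular_formula_counts_hydrogens():
    assert molecular_formula("c1ccccc1O") == ec("C6H6O")
    assert molecular_formula("CC(=O)O") == ec("C2H4O2")


class TestEnumerate:
    def test_2x2x2(self):
        slots = [
            [sub("a1", 1, "C[C:1]"), sub("a2", 1, "O[C:1]")],
            [sub("b1", 2, "[C:1]C[C:2]"), sub("b2", 2, "[C:1]O[C:2]")],
            [sub("c1", 3, "[C:2]C"), sub("c2", 3, "[C:2]O")],
        ]
        lib = enumerate_library(ModuleSet("t", slots), [template(slots=(1, 2, 3))])
        n_dupes = sum(len(v) for v in lib.duplicates.values())
        assert len(lib) + n_dupes == 8

    def test_234_matches_product_rule(self, toy_set_234):
        ms, templates = toy_set_234
        lib = enumerate_library(ms, templates)
        n_dupes = sum(len(v) for v in lib.duplicates.values())
        assert len(lib) + n_dupes == 2 * 3 * 4

    def test_234_matches_nested_loop_oracle(self, toy_set_234):
        ms, templates = toy_set_234
        lib = enumerate_library(ms, templates)
        oracle_smiles = []
        for a in ms.slots[0]:
            for b in ms.slots[1]:
                for c in ms.slots[2]:
                    oracle_smiles.append(assemble_structure(ms, [a, b, c]))
        assert len(oracle_smiles) == 24
        assert {c.smiles for c in lib.compounds} == set(oracle_smiles)

    def test_duplicate_submodule_collapsed(self):
        slots = [
            [sub("a1", 1, "C[C:1]"), sub("a1bis", 1, "C[C:1]")],  # identical fragment
            [sub("b1", 2, "[C:1]O")],
        ]
        lib = enumerate_library(ModuleSet("t", slots), [template(slots=(1, 2))])
        assert len(lib) == 1
        assert sum(len(v) for v in lib.duplicates.values()) == 1

    def test_empty_slot_rejected(self):
        with pytest.raises(ChemError, match="empty"):
            ModuleSet("t", [[sub("a", 1)], []])

    def test_shift_sum_invariant(self, daphnane_lib):
        # every predicted family formula differs from m0 by the chosen shifts
        ms = daphnane_lib.module_set
        for compound in daphnane_lib.compounds[::37]:
            choices = [ms.submodule(cid) for cid in compound.choices]
            for t in daphnane_lib.templates:
                expected = predict_ion_formula(t, choices)
                assert compound.ion(t.id).formula == expected


class TestPersistence:
    @pytest.fixture()
    def toy_lib(self, toy_set_234):
        ms, templates = toy_set_234
        return enumerate_library(ms, templates)

    def test_round_trip_equality(self, toy_lib, tmp_path):
        path = tmp_path / "lib.db"
        persist_library(toy_lib, path)
        back = load_library(path)
        assert len(back) == len(toy_lib)
        assert [c.compound_id for c in back.compounds] == [
            c.compound_id for c in toy_lib.compounds
        ]
        for a, b in zip(back.compounds, toy_lib.compounds):
            assert a.smiles == b.smiles
            assert a.choices == b.choices
            assert a.formula == b.formula
            assert a.ions == b.ions
        assert [t.id for t in back.templates] == [t.id for t in toy_lib.templates]
        assert back.module_set.slot_sizes == toy_lib.module_set.slot_sizes

    def test_lookup_by_formula(self, toy_lib, tmp_path):
        path = tmp_path / "lib.db"
        persist_library(toy_lib, path)
        back = load_library(path)
        target = toy_lib.compounds[0].ions[0].formula
        hits = back.by_ion_formula(target)
        assert toy_lib.compounds[0].compound_id in {c.compound_id for c in hits}

    def test_corrupted_file_clean_error(self, tmp_path):
        path = tmp_path / "junk.db"
        path.write_bytes(b"this is not a sqlite database at all" * 10)
        with pytest.raises(LibraryError):
            load_library(path)

    def test_schema_version_mismatch(self, toy_lib, tmp_path):
        path = tmp_path / "lib.db"
        persist_library(toy_lib, path)
        con = sqlite3.connect(path)
        con.execute("UPDATE meta SET value='999' WHERE key='schema_version'")
        con.commit()
        con.close()
        with pytest.raises(LibraryError, match="999"):
            load_library(path)

    def test_missing_file(self, tmp_path):
        with pytest.raises(LibraryError, match="not found"):
            load_library(tmp_path / "nope.db")


class TestDaphnaneToySet:
    def test_slot_sizes(self, daphnane_lib):
        assert daphnane_lib.module_set.slot_sizes == (4, 3, 3, 4, 3)

    def test_no_duplicate_structures(self, daphnane_lib):
        assert len(daphnane_lib) == 4 * 3 * 3 * 4 * 3

    def test_every_structure_valid(self, daphnane_lib):
        for c in daphnane_lib.compounds[::25]:
            assert Chem.MolFromSmiles(c.smiles) is not None

    def test_diagnostic_windows_disjoint(self, daphnane_lib):
        # all distinct product-ion formulas separated by > 10 ppm
        from mfsa.chem_core import monoisotopic_mass

        masses = sorted(
            monoisotopic_mass(f) for f in daphnane_lib.product_ion_formulas()
        )
        for a, b in itertools.pairwise(masses):
            assert (b - a) / a * 1e6 > 10.0

    def test_core_ion_variants_match_module_design(self, daphnane_lib):
        formulas = {
            c.ion("core_ion").formula.to_string() for c in daphnane_lib.compounds
        }
        assert formulas == {"C17H17O2", "C17H19O2", "C17H21O2", "C17H17O3"}

    def test_macro_loss_variants(self, daphnane_lib):
        formulas = {
            c.ion("macro_loss").formula.to_string() for c in daphnane_lib.compounds
        }
        assert formulas == {"C10H16O2", "C10H14O2", "C10H12O2"}
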