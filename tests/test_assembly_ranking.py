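import pytest

from mfsa.assembly_ranking import (
    AnnotationRule,
    Candidate,
    EvidenceSpec,
    MatchedEvidence,
    annotate,
    apply_rules,
    lookup_candidates,
    rules_from_library,
)
from mfsa.chem_core import ElementCount
from mfsa.labeling import FeatureIonLabel, NeutralLossLabel
from mfsa.pseudo_library import enumerate_library
from mfsa.spectra_io import Spectrum
from mfsa.synthetic_fixtures import SimulationConfig, simulate_dataset


def ec(formula, charge=0):
    return ElementCount.from_string(formula, charge=charge)


def ion_label(formula, score, ppm=0.0):
    return FeatureIonLabel(
        formula=formula, observed_mz=0.0, ppm=ppm,
        normalized_intensity=score, rank=1, score=score,
    )


def loss_label(loss, i1, i2):
    return NeutralLossLabel(ec("C20H25O6", 1), ec("C17H21O4", 1), loss, i1, i2)


CORE = ec("C17H17O2", charge=1)
B_LOSS = ec("C3H4O2")


class TestEvidenceSpec:
    def test_fractional_weight_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            EvidenceSpec("ion", "core", CORE, weight=0.5)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            EvidenceSpec("vibe", "core", CORE)

    def test_rule_needs_evidence(self):
        with pytest.raises(ValueError, match="no evidence"):
            AnnotationRule("r", [], {1: "x"})


class TestApplyRules:
    def _rules(self):
        return [
            AnnotationRule(
                "core/I-a", [EvidenceSpec("ion", "core_ion", CORE)], {1: "I-a"}
            ),
            AnnotationRule(
                "bloss/II-a", [EvidenceSpec("loss", "b_loss", B_LOSS)], {2: "II-a"}
            ),
        ]

    def test_printed_priority_sum(self):
        # ion score 1.0 + loss score 0.36 -> priority 1.36
        ion_labels = {"core_ion": [ion_label(CORE, 1.0)]}
        loss_labels = {"b_loss": [loss_label(B_LOSS, 0.8, 0.4)]}
        (cand,) = apply_rules(ion_labels, loss_labels, self._rules(), n_slots=5)
        assert cand.priority_score == pytest.approx(1.36, abs=1e-12)
        assert cand.choices == {1: ("I-a",), 2: ("II-a",)}

    def test_no_rule_satisfied(self):
        assert apply_rules({}, {}, self._rules(), n_slots=5) == []

    def test_missing_required_evidence_fails_rule(self):
        ion_labels = {"core_ion": [ion_label(CORE, 1.0)]}
        (cand,) = apply_rules(ion_labels, {}, self._rules(), n_slots=5)
        assert cand.choices == {1: ("I-a",)}  # loss rule did not fire

    def test_two_rules_same_submodule_union_evidence(self):
        other = ec("C20H25O6", charge=1)
        rules = [
            AnnotationRule("r1", [EvidenceSpec("ion", "core_ion", CORE)], {1: "I-a"}),
            AnnotationRule("r2", [EvidenceSpec("ion", "c20_ion", other)], {1: "I-a"}),
        ]
        ion_labels = {
            "core_ion": [ion_label(CORE, 0.9)],
            "c20_ion": [ion_label(other, 0.7)],
        }
        (cand,) = apply_rules(ion_labels, {}, rules, n_slots=5)
        assert len(cand.evidence) == 2
        assert cand.priority_score == pytest.approx(1.6, abs=1e-12)

    def test_duplicate_evidence_counted_once(self):
        rules = [
            AnnotationRule("r1", [EvidenceSpec("ion", "core_ion", CORE)], {1: "I-a"}),
            AnnotationRule("r2", [EvidenceSpec("ion", "core_ion", CORE)], {1: "I-a"}),
        ]
        ion_labels = {"core_ion": [ion_label(CORE, 0.9)]}
        (cand,) = apply_rules(ion_labels, {}, rules, n_slots=5)
        assert cand.priority_score == pytest.approx(0.9, abs=1e-12)

    def test_contradictory_assignments_both_kept(self):
        other = ec("C17H19O2", charge=1)
        rules = [
            AnnotationRule("r1", [EvidenceSpec("ion", "core_ion", CORE)], {1: "I-a"}),
            AnnotationRule("r2", [EvidenceSpec("ion", "core_ion", other)], {1: "I-b"}),
        ]
        ion_labels = {"core_ion": [ion_label(CORE, 0.9), ion_label(other, 0.4)]}
        candidates = apply_rules(ion_labels, {}, rules, n_slots=5)
        assert len(candidates) == 2
        assert candidates[0].priority_score >= candidates[1].priority_score
        assert {c.choices[1] for c in candidates} == {("I-a",), ("I-b",)}

    def test_weight_zero_evidence_optional_and_unscored(self):
        rules = [
            AnnotationRule(
                "r1",
                [
                    EvidenceSpec("ion", "core_ion", CORE, weight=1),
                    EvidenceSpec("ion", "c20_ion", ec("C20H25O6", 1), weight=0),
                ],
                {1: "I-a"},
            )
        ]
        ion_labels = {"core_ion": [ion_label(CORE, 0.9)]}
        (cand,) = apply_rules(ion_labels, {}, rules, n_slots=5)
        assert cand.priority_score == pytest.approx(0.9, abs=1e-12)


@pytest.fixture(scope="module")
def toy_lib(toy_set_234):
    return enumerate_library(*toy_set_234)


@pytest.fixture(scope="module")
def dataset(daphnane_lib):
    cfg = SimulationConfig(seed=11, n_members=8, n_decoys=8, ppm_sigma=1.0)
    return simulate_dataset(daphnane_lib, cfg)


class TestLookupCandidates:
    def _candidate(self, choices):
        return Candidate(choices={k: (v,) for k, v in choices.items()}, evidence=[])

    def test_full_vector_unique(self, toy_lib):
        hits = lookup_candidates(
            self._candidate({1: "a1", 2: "b1", 3: "c1"}), toy_lib
        )
        assert len(hits) == 1

    def test_partial_vector_enumeration_oracle(self, toy_lib):
        hits = lookup_candidates(self._candidate({1: "a1", 2: "b2"}), toy_lib)
        oracle = [
            c for c in toy_lib.compounds
            if c.choices[0] == "a1" and c.choices[1] == "b2"
        ]
        assert len(hits) == len(oracle) == 4

    def test_precursor_constraint_excludes_all(self, toy_lib):
        hits = lookup_candidates(
            self._candidate({1: "a1", 2: "b1", 3: "c1"}),
            toy_lib,
            precursor_formula=ec("C50H2"),
        )
        assert hits == []


class TestRulesFromLibrary:
    def test_one_rule_per_single_slot_family_submodule(self, daphnane_lib):
        rules = rules_from_library(daphnane_lib)
        # slots (4,3,3,4,3); families cover slots 1-5 singly; c20_ion covers none
        assert len(rules) == 4 + 3 + 3 + 4 + 3

    def test_rule_formulas_shifted_by_deltas(self, daphnane_lib):
        rules = {r.id: r for r in rules_from_library(daphnane_lib)}
        rule = rules["core_ion/I-oxy"]
        assert rule.evidence[0].formula == ec("C17H17O3", charge=1)
        assert rule.assign == ((1, ("I-oxy",)),)


class TestAnnotatePipeline:
    def test_members_annotated_decoys_absent(self, daphnane_lib, daphnane_rules, dataset):
        table, spectra, truth = dataset
        report = annotate(table, spectra, daphnane_lib, daphnane_rules)
        members = truth[truth.compound_id != ""]
        decoys = set(truth[truth.compound_id == ""].feature_id)
        assert set(report.frame.feature_id) == set(members.feature_id)
        assert not (set(report.frame.feature_id) & decoys)
        for _, row in members.iterrows():
            top = report.top1(row.feature_id)
            assert top is not None and top["smiles"] == row.smiles

    def test_rerun_identical(self, daphnane_lib, daphnane_rules, dataset, tmp_path):
        table, spectra, _ = dataset
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        annotate(table, spectra, daphnane_lib, daphnane_rules).write_csv(p1)
        annotate(table, spectra, daphnane_lib, daphnane_rules).write_csv(p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_empty_input_gives_empty_report_with_headers(
        self, daphnane_lib, daphnane_rules, dataset
    ):
        table, _, _ = dataset
        report = annotate(table, [], daphnane_lib, daphnane_rules)
        assert len(report.frame) == 0
        assert list(report.frame.columns) == report.COLUMNS

    def test_per_feature_failure_isolated(
        self, daphnane_lib, daphnane_rules, dataset, caplog
    ):
        table, spectra, truth = dataset
        # a doubly charged spectrum trips the decomposition guard downstream
        broken = Spectrum(
            feature_id=spectra[0].feature_id,
            precursor_mz=spectra[0].precursor_mz,
            charge=2,
            peaks=spectra[0].peaks,
        )
        report = annotate(table, [broken] + list(spectra[1:]), daphnane_lib, daphnane_rules)
        members = set(truth[truth.compound_id != ""].feature_id)
        assert members - {spectra[0].feature_id} <= set(report.frame.feature_id)

    def test_top_n_caps_candidates(self, daphnane_lib, daphnane_rules, dataset):
        import copy

        table, spectra, _ = dataset
        cfg = copy.deepcopy(daphnane_rules)
        cfg.top_n = 1
        report = annotate(table, spectra, daphnane_lib, cfg)
        counts = report.frame.groupby("feature_id").size()
        assert (counts <= 1).all()

    def test_priority_non_decreasing_with_added_evidence(self):
        base = Candidate(
            choices={1: ("I-a",)},
            evidence=[
                MatchedEvidence(EvidenceSpec("ion", "core_ion", CORE), 0.5, 0.0)
            ],
        )
        more = Candidate(
            choices={1: ("I-a",)},
            evidence=base.evidence
            + [MatchedEvidence(EvidenceSpec("loss", "b_loss", B_LOSS), 0.2, None)],
        )
        assert more.priority_score >= base.priority_score
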