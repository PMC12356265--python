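import pytest

from mfsa.app import packaged_data
from mfsa.assembly_ranking import load_rules_config
from mfsa.chem_core import ElementCount, ElementDelta
from mfsa.formula_adduct import FormulaRanges, build_formula_db
from mfsa.pseudo_library import (
    IonFamilyTemplate,
    ModuleSet,
    SubModule,
    enumerate_library,
    load_module_config,
)
from mfsa.spectra_io import Peak, Spectrum


@pytest.fixture(scope="session")
def daphnane_modules():
    return load_module_config(packaged_data("daphnane_modules.yaml"))


@pytest.fixture(scope="session")
def daphnane_lib(daphnane_modules):
    ms, templates = daphnane_modules
    return enumerate_library(ms, templates)


@pytest.fixture(scope="session")
def daphnane_rules(daphnane_lib):
    return load_rules_config(packaged_data("daphnane_rules.yaml"), daphnane_lib)


@pytest.fixture(scope="session")
def small_db():
    return build_formula_db(FormulaRanges(C=(0, 15), H=(0, 25), O=(0, 6), N=(0, 2)))


def _sub(sid, slot, smiles, family=None, delta=None):
    deltas = {family: ElementDelta(delta)} if family else {}
    return SubModule(sid, slot, smiles, deltas)


@pytest.fixture(scope="session")
def toy_set_234():
    """Three slots of sizes (2, 3, 4); every combination assembles."""
    slots = [
        [
            _sub("a1", 1, "C[C:1]", "ion", {"H": 0}),
            _sub("a2", 1, "O[C:1]", "ion", {"O": 1}),
        ],
        [
            _sub("b1", 2, "[C:1]O[C:2]", "ion", {"H": 0}),
            _sub("b2", 2, "[C:1]S[C:2]", "ion", {"H": 2}),
            _sub("b3", 2, "[C:1]C(=O)[C:2]", "ion", {"C": 1}),
        ],
        [
            _sub("c1", 3, "[C:2]", "ion", {"H": 0}),
            _sub("c2", 3, "[C:2]C", "ion", {"C": 1, "H": 2}),
            _sub("c3", 3, "[C:2]O", "ion", {"O": 1}),
            _sub("c4", 3, "[C:2]CC", "ion", {"C": 2, "H": 4}),
        ],
    ]
    templates = [
        IonFamilyTemplate(
            "ion", "product_ion", ElementCount.from_string("C5H9O", charge=1),
            slots=(1, 2, 3),
        )
    ]
    return ModuleSet("toy234", slots), templates


def make_spectrum(peaks, feature_id="S1", precursor_mz=500.0, **kw):
    return Spectrum(
        feature_id=feature_id,
        precursor_mz=precursor_mz,
        peaks=tuple(Peak(mz, i) for mz, i in peaks),
        **kw,
    )
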