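"""Seeded synthetic datasets emulating MZmine exports.

Spectra are simulated directly from a pseudo-compound's predicted
diagnostic families: product-ion peaks near the top of the intensity
range, neutral losses realized as their implied ion pairs, noise kept
below the default 0.1 floor so the noiseless pipeline recovers every
family exactly.  Decoy spectra avoid every diagnostic m/z window of the
library by construction.  All randomness flows from one integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from mfsa.chem_core import ChemError, ElementCount, monoisotopic_mass
from mfsa.formula_adduct import DEFAULT_ADDUCTS, adduct_mz
from mfsa.pseudo_library import (
    NEUTRAL_LOSS,
    PRODUCT_ION,
    ModuleSet,
    PseudoCompound,
    PseudoLibrary,
    SubModule,
    enumerate_library,
)
from mfsa.spectra_io import FeatureTable, Peak, Spectrum

__all__ = [
    "SimulationConfig",
    "simulate_spectrum",
    "simulate_dataset",
    "degrade_library",
]

_PROTONATED = DEFAULT_ADDUCTS[0]  # [M+H]+


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_members: int = 50
    n_decoys: int = 50
    noise_peaks: int = 6
    noise_intensity_ceiling: float = 0.08  # fraction of the range maximum
    diag_intensity_range: tuple[float, float] = (0.5, 1.0)
    ppm_sigma: float = 0.0
    dropout: float = 0.0
    base_intensity: float = 1.0e6
    noise_mz_range: tuple[float, float] = (200.0, 400.0)
    decoy_mz_range: tuple[float, float] = (150.0, 800.0)
    decoy_peaks: int = 12
    rt_range: tuple[float, float] = (1.0, 15.0)
    guard_ppm: float = 20.0  # keep noise/decoys this far from diagnostic windows

    def __post_init__(self) -> None:
        if not (0.0 <= self.dropout <= 1.0):
            raise ValueError("dropout must lie in [0, 1]")
        if self.ppm_sigma < 0:
            raise ValueError("ppm_sigma must be >= 0")


def _jitter(mz: float, cfg: SimulationConfig, rng: np.random.Generator) -> float:
    if cfg.ppm_sigma == 0:
        return mz
    return mz * (1.0 + rng.normal(0.0, cfg.ppm_sigma) / 1e6)


def _diagnostic_mz_values(lib: PseudoLibrary) -> np.ndarray:
    """Every m/z the pipeline might match: ions, loss partners, precursors."""
    values: set[float] = set()
    for compound in lib.compounds:
        for mz in _expected_peaks(compound, lib):
            values.add(mz)
        values.add(adduct_mz(compound.formula, _PROTONATED))
    return np.array(sorted(values))


def _expected_peaks(
    compound: PseudoCompound, lib: PseudoLibrary
) -> dict[float, str]:
    """Theoretical diagnostic peak m/z -> family provenance."""
    out: dict[float, str] = {}
    precursor_ion = compound.formula + ElementCount({"H": 1}, charge=1)
    for di in compound.ions:
        if di.kind == PRODUCT_ION:
            out[monoisotopic_mass(di.formula)] = di.family_id
        elif di.kind == NEUTRAL_LOSS:
            template = lib.template(di.family_id)
            if template.parent_family == "precursor":
                parent = precursor_ion
            else:
                parent = compound.ion(template.parent_family).formula
            try:
                partner = parent - di.formula
            except ChemError:
                continue  # loss larger than the parent ion; no pair realized
            out[monoisotopic_mass(partner)] = f"{di.family_id}:partner"
    return out


def simulate_spectrum(
    compound: PseudoCompound,
    lib: PseudoLibrary,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    feature_id: str,
    avoid_mz: np.ndarray | None = None,
) -> Spectrum:
    """One MS/MS spectrum realizing every diagnostic family of a compound.

    Peaks appear at predicted ion m/z (ppm-jittered), loss families as
    their implied ion pairs, plus the protonated precursor and uniform
    sub-floor noise.  Deterministic for a given (rng state, compound).
    """
    if not compound.ions:
        raise ValueError(f"compound {compound.compound_id} has no diagnostic ions")
    lo, hi = cfg.diag_intensity_range
    peaks: list[Peak] = []
    precursor_mz = adduct_mz(compound.formula, _PROTONATED)
    for theo_mz in sorted(_expected_peaks(compound, lib)):
        if rng.random() < cfg.dropout:
            continue
        intensity = rng.uniform(lo, hi) * cfg.base_intensity
        peaks.append(Peak(_jitter(theo_mz, cfg, rng), intensity))
    peaks.append(
        Peak(
            _jitter(precursor_mz, cfg, rng),
            rng.uniform(lo, hi) * cfg.base_intensity,
        )
    )
    guard = avoid_mz if avoid_mz is not None else np.array([])
    n_min, n_max = cfg.noise_mz_range
    for _ in range(cfg.noise_peaks):
        mz = _draw_clear_mz(rng, n_min, n_max, guard, cfg.guard_ppm)
        peaks.append(
            Peak(mz, rng.uniform(0.0, cfg.noise_intensity_ceiling) * cfg.base_intensity)
        )
    return Spectrum(
        feature_id=feature_id,
        precursor_mz=_jitter(precursor_mz, cfg, rng),
        charge=1,
        rt=rng.uniform(*cfg.rt_range),
        peaks=tuple(peaks),
        polarity="+",
    )


def _draw_clear_mz(
    rng: np.random.Generator,
    mz_min: float,
    mz_max: float,
    avoid: np.ndarray,
    guard_ppm: float,
    max_tries: int = 1000,
) -> float:
    for _ in range(max_tries):
        mz = rng.uniform(mz_min, mz_max)
        if avoid.size == 0:
            return mz
        nearest = avoid[np.abs(avoid - mz).argmin()]
        if abs(mz - nearest) / nearest * 1e6 > guard_ppm:
            return mz
    raise RuntimeError("could not draw an m/z clear of diagnostic windows")


def _simulate_decoy(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    feature_id: str,
    avoid_mz: np.ndarray,
) -> Spectrum:
    d_min, d_max = cfg.decoy_mz_range
    peaks = [
        Peak(
            _draw_clear_mz(rng, d_min, d_max, avoid_mz, cfg.guard_ppm),
            rng.uniform(0.05, 1.0) * cfg.base_intensity,
        )
        for _ in range(cfg.decoy_peaks)
    ]
    precursor = _draw_clear_mz(rng, 300.0, d_max, avoid_mz, cfg.guard_ppm)
    return Spectrum(
        feature_id=feature_id,
        precursor_mz=precursor,
        charge=1,
        rt=rng.uniform(*cfg.rt_range),
        peaks=tuple(peaks),
        polarity="+",
    )


def simulate_dataset(
    lib: PseudoLibrary, cfg: SimulationConfig
) -> tuple[FeatureTable, list[Spectrum], pd.DataFrame]:
    """Members plus decoys as (feature table, spectra, truth table).

    The truth table maps feature_id to the generating compound (empty
    for decoys).  Compound selection, intensities, jitter and noise all
    derive from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    avoid = _diagnostic_mz_values(lib)
    n_compounds = len(lib.compounds)
    if cfg.n_members <= n_compounds:
        picks = rng.choice(n_compounds, size=cfg.n_members, replace=False)
    else:
        picks = rng.choice(n_compounds, size=cfg.n_members, replace=True)
    spectra: list[Spectrum] = []
    truth_rows: list[dict] = []
    table_rows: list[dict] = []
    for i, pick in enumerate(picks, start=1):
        compound = lib.compounds[int(pick)]
        fid = f"F{i:04d}"
        s = simulate_spectrum(compound, lib, cfg, rng, fid, avoid)
        spectra.append(s)
        truth_rows.append(
            {
                "feature_id": fid,
                "compound_id": compound.compound_id,
                "smiles": compound.smiles,
                "formula": compound.formula.to_string(),
            }
        )
        table_rows.append(
            {
                "feature_id": fid,
                "mz": s.precursor_mz,
                "rt": s.rt,
                "area_sample1": float(rng.uniform(1e5, 1e7)),
            }
        )
    for j in range(1, cfg.n_decoys + 1):
        fid = f"F{cfg.n_members + j:04d}"
        s = _simulate_decoy(cfg, rng, fid, avoid)
        spectra.append(s)
        truth_rows.append(
            {"feature_id": fid, "compound_id": "", "smiles": "", "formula": ""}
        )
        table_rows.append(
            {
                "feature_id": fid,
                "mz": s.precursor_mz,
                "rt": s.rt,
                "area_sample1": float(rng.uniform(1e5, 1e7)),
            }
        )
    table = FeatureTable(pd.DataFrame(table_rows))
    truth = pd.DataFrame(truth_rows)
    return table, spectra, truth


def degrade_library(
    lib: PseudoLibrary, fraction: float, seed: int
) -> PseudoLibrary:
    """Randomly reduce submodule coverage to a fraction per slot.

    Retention count is round-half-up of ``fraction * slot size`` with a
    floor of one submodule per slot; the reduced module set is then
    re-enumerated so indexes and predictions stay consistent.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must lie in (0, 1]")
    if fraction == 1.0:
        return lib
    rng = np.random.default_rng(seed)
    new_slots: list[list[SubModule]] = []
    for slot in lib.module_set.slots:
        keep = max(1, int(math.floor(fraction * len(slot) + 0.5)))
        idx = sorted(rng.choice(len(slot), size=min(keep, len(slot)), replace=False))
        new_slots.append([slot[i] for i in idx])
    reduced = ModuleSet(f"{lib.module_set.name}", new_slots)
    return enumerate_library(reduced, lib.templates)
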