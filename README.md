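# mfsa

Modular fragmentation-based structure assembly (MFSA) for targeted MS/MS
annotation of complex natural products.

The package builds a combinatorial *pseudo-compound library* from a
module-set definition (labeled SMILES fragments per module slot plus an
element mass-shift matrix per diagnostic ion family), then runs a
targeted annotation pipeline over MZmine-style LC-MS/MS exports:

1. **Target recognition** — diagnostic product-ion formulas matched at
   ±5 ppm inside a max-min-normalized m/z window, thresholded on the
   number of matching ions.
2. **De novo formula / adduct assignment** — exhaustive CHON
   enumeration, standard ESI adducts, smallest-|ppm| winner within a
   hydrogen-deficiency-index plausibility range.
3. **Evidence labeling** — carbon-count-constrained neutral-loss ion
   pairs scored `IA × IDF`, feature-ion labels scored `I / Imax`, and a
   range-limited cosine similarity.
4. **Assembly & ranking** — user-defined rules convert labels into
   module assignments; matching library structures are ranked by
   `priority = Σ wᵢsᵢ (ions) + Σ wⱼsⱼ (losses)` with binary weights.

A desk-scale daphnane-like module system (5 slots, 17 submodules, 432
structures) ships with the package as the default example, together
with a synthetic fixture generator so the whole pipeline is testable
offline.

## CLI

```sh
# enumerate the packaged example library into a SQLite store
mfsa build-library --out lib.db

# generate a synthetic dataset (quant.csv + spectra.mgf + truth.csv)
mfsa simulate --library lib.db --seed 1 --n-members 50 --n-decoys 50 \
              --ppm-sigma 1.0 --out fixtures/

# full pipeline: recognition -> formula -> labeling -> ranking
mfsa annotate --csv fixtures/quant.csv --mgf fixtures/spectra.mgf \
              --library lib.db --top-n 3 --out report/

# individual stages
mfsa recognize --library lib.db --mgf fixtures/spectra.mgf --out hits.csv
mfsa assign --mz 361.1646 --polarity pos
mfsa label --library lib.db --mgf fixtures/spectra.mgf --out labels.csv
```

Every command writes a `run_manifest.json` echoing its parameters.
Thresholds (ppm tolerance, normalization range, noise floor, matching
threshold, Top-N, element bounds) live in a rules YAML
(`src/mfsa/data/daphnane_rules.yaml` is the packaged default;
`rules: auto` derives one annotation rule per single-slot ion-family /
submodule pair from the library). Custom module systems are plain YAML
(`src/mfsa/data/daphnane_modules.yaml` shows the format).

## Layout

| module | role |
| --- | --- |
| `mfsa.chem_core` | element-count arithmetic, monoisotopic mass, ppm windows, RDBE |
| `mfsa.spectra_io` | MGF + MZmine quant-CSV IO, max-min normalization |
| `mfsa.pseudo_library` | fragment merging, ion-formula prediction, enumeration, SQLite store |
| `mfsa.recognition` | diagnostic-ion matching and class recognition |
| `mfsa.formula_adduct` | CHON enumeration, adducts, precursor assignment, peak decomposition |
| `mfsa.labeling` | neutral-loss / feature-ion labels, range cosine |
| `mfsa.assembly_ranking` | rules, candidate lookup, priority-score ranking, reports |
| `mfsa.synthetic_fixtures` | seeded dataset simulation, library degradation harness |
| `mfsa.app` | click CLI |
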