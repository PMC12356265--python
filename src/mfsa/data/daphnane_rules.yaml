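# Default rule-set configuration for the daphnane-like toy module system.
# `rules: auto` derives one rule per (single-slot ion family, submodule):
# observing that family's shifted formula assigns the submodule.
name: daphnane-default
polarity: pos
tol_ppm: 5.0
cosine_tol_ppm: 10.0
normalization_range: [200.0, 400.0]
noise_threshold: 0.1
min_matching_ions: 2
top_n: 3
rdbe_range: [0.0, 40.0]
# Daphnanes are nitrogen-free; keep N at zero for formula decomposition.
formula_ranges: {C: [0, 40], H: [0, 60], O: [0, 15], N: [0, 0]}
rules: auto
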