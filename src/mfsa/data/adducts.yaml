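# Standard ESI adducts: five positive-mode, two negative-mode.
- {name: "[M+H]+",        polarity: pos, gained: H,     charge: 1}
- {name: "[M+NH4]+",      polarity: pos, gained: NH4,   charge: 1}
- {name: "[M+H-H2O]+",    polarity: pos, gained: H, lost: H2O, charge: 1}
- {name: "[M+CH3CN+H]+",  polarity: pos, gained: C2H4N, charge: 1}
- {name: "[M+CH3NH2+H]+", polarity: pos, gained: CH6N,  charge: 1}
- {name: "[M-H]-",        polarity: neg, lost: H,       charge: -1}
- {name: "[M+HCOO]-",     polarity: neg, gained: CHO2,  charge: -1}
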