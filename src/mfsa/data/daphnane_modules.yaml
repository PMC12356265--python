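# Desk-scale daphnane-like module system (toy).
#
# Five module slots mirror the diterpenoid disassembly logic: a fused
# A-ring block carrying the C17 core-ion variants, a seven-membered
# B-ring block expressed as a small neutral loss off the C20 skeleton
# ion, a C-ring block with its own skeleton ion, an acyl substituent
# block, and a macrocycle block expressed as C10HxO2 losses off the
# precursor.  Fragment SMILES share attachment atoms via atom-map
# labels; each submodule lists its element-shift row per ion family.
name: daphnane-toy
modules:
  - index: 1
    name: ring-A block (C17 core-ion variants)
    submodules:
      - id: I-enone
        label: 1,2-en-3-one A ring
        smiles: "O=C1C=C[C:1][C:2]C1"
        deltas:
          core_ion: {C: 0, H: 0, O: 0, N: 0}
      - id: I-enol
        label: 3-hydroxy-1,2-ene A ring
        smiles: "OC1C=C[C:1][C:2]C1"
        deltas:
          core_ion: {H: 2}
      - id: I-saturated
        label: saturated 3-one A ring
        smiles: "O=C1CC[C:1][C:2]C1"
        deltas:
          core_ion: {H: 4}
      - id: I-oxy
        label: extra-oxygenated A ring
        smiles: "O=C1C(O)=C[C:1][C:2]C1"
        deltas:
          core_ion: {O: 1}
  - index: 2
    name: ring-B block (B-ring loss variants)
    submodules:
      - id: II-keto
        label: 5-oxo B ring
        smiles: "[C:1]1[C:2]CC(=O)C[C:3][C:4]1"
        deltas:
          b_loss: {C: 0, H: 0, O: 0, N: 0}
      - id: II-hydroxy
        label: 5-hydroxy B ring
        smiles: "[C:1]1[C:2]CC(O)C[C:3][C:4]1"
        deltas:
          b_loss: {O: 1}
      - id: II-plain
        label: unsubstituted B ring
        smiles: "[C:1]1[C:2]CCC[C:3][C:4]1"
        deltas:
          b_loss: {H: 2, O: -1}
  - index: 3
    name: ring-C block
    submodules:
      - id: III-plain
        label: unsubstituted C ring
        smiles: "[C:3]1[C:4]C[C:5]C[C:6]1"
        deltas:
          cring_ion: {C: 0, H: 0, O: 0, N: 0}
      - id: III-hydroxy
        label: hydroxylated C ring
        smiles: "[C:3]1[C:4]C(O)[C:5]C[C:6]1"
        deltas:
          cring_ion: {O: 1}
      - id: III-methyl
        label: methylated C ring
        smiles: "[C:3]1[C:4]C(C)[C:5]C[C:6]1"
        deltas:
          cring_ion: {C: 1, H: 2}
  - index: 4
    name: acyl substituent block
    submodules:
      - id: IV-acetoxy
        label: acetoxy substituent
        smiles: "[C:5]OC(C)=O"
        deltas:
          acyl_ion: {C: 0, H: 0, O: 0, N: 0}
      - id: IV-propanoyloxy
        label: propanoyloxy substituent
        smiles: "[C:5]OC(=O)CC"
        deltas:
          acyl_ion: {C: 1, H: 2}
      - id: IV-benzoyloxy
        label: benzoyloxy substituent
        smiles: "[C:5]OC(=O)C1=CC=CC=C1"
        deltas:
          acyl_ion: {C: 5, H: 2}
      - id: IV-hydroxy
        label: free hydroxyl
        smiles: "[C:5]O"
        deltas:
          acyl_ion: {C: -1, H: -2, O: -1}
  - index: 5
    name: macrocycle block (loss variants)
    submodules:
      - id: V-mono
        label: mono-oxygenated macrocycle
        smiles: "[C:6]1CCCCC(O)CCCCC1"
        deltas:
          macro_loss: {C: 0, H: 0, O: 0, N: 0}
      - id: V-di
        label: di-oxygenated macrocycle
        smiles: "[C:6]1CCCC(O)CC(O)CCCC1"
        deltas:
          macro_loss: {H: -2}
      - id: V-tri
        label: tri-oxygenated macrocycle
        smiles: "[C:6]1CCC(O)CC(O)CC(O)CCC1"
        deltas:
          macro_loss: {H: -4}
templates:
  - id: core_ion
    kind: product_ion
    m0: C17H17O2
    charge: 1
    slots: [1]
    mz_range: [200.0, 400.0]
  - id: c20_ion
    kind: product_ion
    m0: C20H25O6
    charge: 1
    slots: []
    mz_range: [200.0, 400.0]
  - id: cring_ion
    kind: product_ion
    m0: C14H17O4
    charge: 1
    slots: [3]
    mz_range: [200.0, 400.0]
  - id: acyl_ion
    kind: product_ion
    m0: C13H13O2
    charge: 1
    slots: [4]
    mz_range: [150.0, 400.0]
  - id: b_loss
    kind: neutral_loss
    m0: C3H4O2
    slots: [2]
    parent: c20_ion
    mz_range: [200.0, 400.0]
    c_hi: [20]
    c_lo: [17]
  - id: macro_loss
    kind: neutral_loss
    m0: C10H16O2
    slots: [5]
    parent: precursor
    mz_range: [200.0, 900.0]
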