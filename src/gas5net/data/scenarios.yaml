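# Named perturbation scenarios for the GAS5 G1/S-checkpoint model, with the
# qualitative fixed-point expectations each one must reproduce.
#
# Clamps: KO = clamp 0 (loss of function), E1 = clamp 1 (ectopic
# expression / gain of function). The DNA-damage input is never clamped;
# every scenario is run at both input values ("off" and "on").
#
# Expectation kinds:
#   count      - number of fixed points at the given input value
#   phenotypes - sorted phenotype labels of those fixed points
#   node       - a node value that must hold in: all fixed points ("all"),
#                at least one ("any"), or those with a given phenotype
#                ("phenotype:<label>").
scenarios:

- name: WT
  clamps: {}
  expectations:
  - {kind: count, damage: "off", equals: 1}
  - {kind: count, damage: "on", equals: 2}
  - {kind: phenotypes, damage: "off", equals: [proliferative]}
  - {kind: phenotypes, damage: "on", equals: [apoptotic, arrest]}
  # damage OFF: only the cell-cycle enhancers are active
  - {kind: node, damage: "off", scope: all, node: CDK46_CycD, value: 1}
  - {kind: node, damage: "off", scope: all, node: CDK2_CycE, value: 1}
  - {kind: node, damage: "off", scope: all, node: Cdc25A, value: 1}
  - {kind: node, damage: "off", scope: all, node: HDAC1, value: 1}
  - {kind: node, damage: "off", scope: all, node: Myc, value: 1}
  - {kind: node, damage: "off", scope: all, node: E2F1, value: 1}
  - {kind: node, damage: "off", scope: all, node: GAS5, value: 0}
  - {kind: node, damage: "off", scope: all, node: miR34c, value: 0}
  # damage ON: the GAS5 -> E2F1 -| miR-34c axis is engaged in both fates
  - {kind: node, damage: "on", scope: all, node: GAS5, value: 1}
  - {kind: node, damage: "on", scope: all, node: E2F1, value: 0}
  - {kind: node, damage: "on", scope: all, node: miR34c, value: 1}

- name: GAS5_E1
  clamps: {GAS5: 1}
  expectations:
  - {kind: phenotypes, damage: "on", equals: [apoptotic, arrest]}
  - {kind: node, damage: "on", scope: all, node: E2F1, value: 0}
  - {kind: node, damage: "on", scope: all, node: miR34c, value: 1}
  - {kind: node, damage: "on", scope: all, node: RB1, value: 1}
  - {kind: node, damage: "on", scope: "phenotype:arrest", node: p21, value: 1}

- name: GAS5_KO
  clamps: {GAS5: 0}
  expectations:
  - {kind: phenotypes, damage: "on", equals: [proliferative]}
  - {kind: node, damage: "on", scope: all, node: E2F1, value: 1}
  - {kind: node, damage: "on", scope: all, node: miR34c, value: 0}
  - {kind: node, damage: "on", scope: all, node: RB1, value: 0}
  - {kind: node, damage: "on", scope: all, node: p21, value: 0}

- name: E2F1_KO
  clamps: {E2F1: 0}
  expectations:
  - {kind: phenotypes, damage: "on", equals: [apoptotic, arrest]}
  - {kind: node, damage: "on", scope: all, node: miR34c, value: 1}
  - {kind: node, damage: "on", scope: "phenotype:arrest", node: p21, value: 1}
  - {kind: node, damage: "on", scope: "phenotype:arrest", node: RB1, value: 1}

- name: E2F1_E1
  clamps: {E2F1: 1}
  expectations:
  - {kind: phenotypes, damage: "on", equals: [proliferative]}
  - {kind: node, damage: "on", scope: all, node: miR34c, value: 0}
  - {kind: node, damage: "on", scope: all, node: RB1, value: 0}
  - {kind: node, damage: "on", scope: all, node: p21, value: 0}

- name: miR34c_E1
  clamps: {miR34c: 1}
  expectations:
  - {kind: phenotypes, damage: "on", equals: [apoptotic, arrest]}
  # GAS5 follows the input exactly as in the wild type
  - {kind: node, damage: "off", scope: all, node: GAS5, value: 0}
  - {kind: node, damage: "on", scope: all, node: GAS5, value: 1}

- name: miR34c_KO
  clamps: {miR34c: 0}
  note: >-
    Reported in-vivo/in-vitro reading is enhanced apoptosis; the
    reconstructed rules instead yield a proliferative damage-ON fixed
    point (de-repression of the cell-cycle program). Flagged as a known
    model/literature discrepancy rather than forced.
  expectations:
  - {kind: phenotypes, damage: "on", equals: [proliferative]}
  - {kind: node, damage: "off", scope: all, node: GAS5, value: 0}
  - {kind: node, damage: "on", scope: all, node: GAS5, value: 1}

- name: HDAC1_KO
  clamps: {HDAC1: 0}
  expectations:
  - {kind: phenotypes, damage: "on", equals: [apoptotic, arrest]}
  - {kind: node, damage: "on", scope: all, node: miR34c, value: 1}
  - {kind: node, damage: "on", scope: "phenotype:arrest", node: p21, value: 1}

- name: HDAC1_E1
  clamps: {HDAC1: 1}
  expectations:
  - {kind: phenotypes, damage: "on", equals: [apoptotic]}
  - {kind: node, damage: "on", scope: all, node: p21, value: 0}

- name: p53_KO
  clamps: {p53: 0}
  expectations:
  - {kind: phenotypes, damage: "on", equals: [apoptotic, arrest]}
  - {kind: node, damage: "on", scope: all, node: miR34c, value: 1}
  - {kind: node, damage: "on", scope: "phenotype:arrest", node: p21, value: 1}
  - {kind: node, damage: "on", scope: "phenotype:arrest", node: RB1, value: 1}

- name: p38_KO
  clamps: {p38MAPK: 0}
  expectations:
  - {kind: phenotypes, damage: "on", equals: [proliferative]}
  - {kind: node, damage: "on", scope: all, node: GAS5, value: 1}
  - {kind: node, damage: "on", scope: all, node: E2F1, value: 1}
  - {kind: node, damage: "on", scope: all, node: miR34c, value: 0}

- name: p38_E1
  clamps: {p38MAPK: 1}
  expectations:
  - {kind: phenotypes, damage: "on", equals: [apoptotic, arrest]}
  - {kind: node, damage: "on", scope: all, node: miR34c, value: 1}

- name: ATM_KO
  clamps: {ATM: 0}
  expectations:
  - {kind: phenotypes, damage: "on", equals: [proliferative]}
  - {kind: node, damage: "on", scope: all, node: GAS5, value: 1}
  - {kind: node, damage: "on", scope: all, node: E2F1, value: 1}
  - {kind: node, damage: "on", scope: all, node: miR34c, value: 0}

- name: ATM_E1
  clamps: {ATM: 1}
  expectations:
  - {kind: phenotypes, damage: "on", equals: [apoptotic, arrest]}
  - {kind: node, damage: "on", scope: all, node: miR34c, value: 1}

- name: p38_E1__p53_KO
  clamps: {p38MAPK: 1, p53: 0}
  expectations:
  - {kind: phenotypes, damage: "on", equals: [apoptotic, arrest]}
  - {kind: node, damage: "on", scope: all, node: miR34c, value: 1}
  - {kind: node, damage: "on", scope: all, node: RB1, value: 1}
  - {kind: node, damage: "on", scope: "phenotype:arrest", node: p21, value: 1}

- name: ATM_E1__p53_KO
  clamps: {ATM: 1, p53: 0}
  expectations:
  - {kind: phenotypes, damage: "on", equals: [apoptotic, arrest]}
  - {kind: node, damage: "on", scope: all, node: miR34c, value: 1}
  - {kind: node, damage: "on", scope: all, node: RB1, value: 1}
  - {kind: node, damage: "on", scope: "phenotype:arrest", node: p21, value: 1}
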