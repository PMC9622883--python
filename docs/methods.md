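# Methods

## Model class and update semantics

`gas5net` works with Boolean (logical) models of gene regulation: each
molecule is a binary variable (0 = inactive/absent, 1 = active/present) with
one update rule over its regulators, written with AND/OR/NOT. Updates are
synchronous — all nodes recompute simultaneously from the current state — so
the dynamics is a deterministic self-map of the finite state space {0,1}^n.
The observables are the attractors: fixed points (states mapped to
themselves) and, for small networks, the cycles of the state-transition
graph. Fixed points are identical under synchronous and asynchronous
schemes, which the engine uses as a built-in soundness check
(`verify_fixed_point_asynchronous`).

In-silico perturbations follow the standard logical-modelling convention:
loss of function (KO) replaces a node's rule with the constant 0, gain of
function / ectopic expression (E1) with the constant 1, permanently. Clamped
nodes therefore hold their value from the first update onward; their original
regulators remain visible in the rule file for audit but drop out of the
dynamical edge set.

## The G1/S-checkpoint network

The shipped model (`src/gas5net/data/gas5_gc.bnet`) has 26 nodes and 73
regulator→target interactions: one free input (`DNA_damage`, modelled with
the self-rule `DNA_damage, DNA_damage` so that each input value closes its
own dynamics), 22 molecular species, and three output readouts
(`Proliferation`, `CellCycleArrest`, `Apoptosis`). Both counts, the unique
input and the output roster are re-asserted every time the model is loaded.

Structural choices that were genuinely open and how they were resolved:

* **Node roster.** The narrative sources name slightly more than 26
  molecules. Two consolidations bring the roster to exactly 26: the
  pro-apoptotic effectors PUMA and Bax are carried by a single `Bax` node
  (one PUMA/BAX effector arm feeding caspase), and Cyclin D1 lives inside
  the `CDK46_CycD` complex node (so GAS5's repression of the CycD program
  is carried through p21). Canonical identifiers use `[A-Za-z0-9_]` only;
  the display-name map (`gas5_gc_nodes.tsv`) preserves conventional
  typography such as "cdk4/6-CycD" and "miR-34c".
* **Damage sensing.** `ATM = DNA_damage`, `p38MAPK = ATM`,
  `GAS5 = DNA_damage`: GAS5 induction is damage-dependent but not
  ATM-dependent, which is what lets ATM/p38 knockdowns show an induced yet
  functionally inert GAS5.
* **The GAS5 → E2F1 ⊣ miR-34c axis.** E2F1 needs Myc and phosphorylated
  (inactive) RB1, and is silenced by GAS5 *only when p38 MAPK signalling is
  active* (`!(GAS5 & p38MAPK)`). The conjunction encodes the observation
  that GAS5's tumor-suppressor function is ATM/p38-dependent: with p38 (or
  ATM) knocked down, damage still induces GAS5 but E2F1 stays on and the
  cell keeps proliferating. Symmetrically, miR-34c requires the full
  GAS5-licensed damage signal and release from E2F1 repression
  (`GAS5 & ATM & p38MAPK & !E2F1`).
* **Two coupled bistable switches.** The arrest-vs-apoptosis decision is
  carried by (i) the p53 phosphoform switch — arrester `p53_A`
  (Ser-15/20, ATM-dependent) and killer `p53_K` (Ser-46, p38-dependent,
  requiring p53-INP1 and reverted by Wip1) exclude each other through the
  Wip1/p53-INP1 circuit — and (ii) the p53-independent p21/caspase mutual
  inhibition (p21 blocks caspase; active caspase cleaves p38-driven p21,
  while p53-A-driven p21 resists cleavage). Switch (ii) is what keeps both
  damage fates reachable when p53 is knocked out.
* **Deacetylase gating.** Sirt1 and HDAC1 (both miR-34c targets) block p53
  activation; this is what shuts the p53 arm down in every scenario where
  miR-34c is absent, preventing spurious apoptotic fixed points in
  proliferative mutants (e.g. E2F1 E1, GAS5 KO).
* **Outputs.** `Proliferation = Myc & CDK46_CycD & CDK2_CycE & Cdc25A`;
  `CellCycleArrest = (p21 | RB1) & !Caspase` (apoptotic execution
  suppresses the arrest readout, so fates print as clean one-hot rows);
  `Apoptosis = Caspase & !Bcl2`.

Every rule in `gas5_gc.bnet` carries a comment stating the biological
interaction it encodes. Where the choice between AND and OR among
co-regulators was not dictated by the narrative, it was calibrated once so
that the full set of published qualitative fixed-point behaviours (wild type
plus all knockdown/overexpression signatures) holds simultaneously, then
frozen; the regression suite pins all of them.

### Phenotype labels

A fixed point is labelled from its output bits: (1,0,0) proliferative,
(0,1,0) arrest, (0,0,1) apoptotic; apoptosis dominates arrest if both bits
are ever set, proliferation co-occurring with a damage fate would be
"mixed", and (0,0,0) is "null". The shipped model only ever exhibits the
three one-hot patterns (plus a damage-OFF arrest state under forced
miR-34c).

### Known discrepancy

For miR-34c KO under damage the model yields a proliferative fixed point —
the expected direction for losing a tumor suppressor — whereas the
experimental literature the scenario mirrors reports enhanced apoptosis.
The rules encode what the reconstructed logic actually produces; the
scenario carries a note in the suite report rather than a forced
expectation.

## Algorithms

* **Exhaustive fixed-point search** enumerates all 2^n states with
  per-rule compiled evaluators; capped at n = 22 by default.
* **Constraint search** solves the conjunction of `v ↔ f_v` constraints:
  three-valued (Kleene) rule evaluation propagates forced values to a
  fixpoint, then the solver branches on the undetermined node with the
  most unresolved dependents. The search is complete; every total
  assignment is re-verified against the compiled update map before being
  reported. Agreement with exhaustive enumeration is property-tested on
  hundreds of seeded random networks at every test run.
* **Cycle detection** builds on the functional nature of the synchronous
  STG: terminal SCCs are exactly the cycles reached by iterated
  successors, found with a colored walk in O(2^n); capped at n = 16 and
  deliberately not used for the 26-node model, whose published claims
  concern fixed points only.
* **Determinism.** Reports are sorted lexicographically over the canonical
  node order, so results are a pure function of the network, never of
  branching order. All TSV/heatmap output is integer-valued and
  byte-stable across reruns.

## Synthetic networks

`synth` generates seeded random Boolean networks (n nodes, k regulators
sampled without replacement, rule schemes: uniformly random non-constant
truth tables, nested-canalizing, or sign-respecting
OR(activators) & !OR(inhibitors) mirroring activation/inhibition arcs).
The PRNG is Python's `random.Random` (MT19937) with integer seeding, which
is portable across platforms, so spec+seed pairs reproduce byte-identical
`.bnet` files. These ensembles exist to exercise the engine (solver
equivalence, asynchronous invariance, re-entry bounds) independently of the
checkpoint model; they make no claim to the statistics of real regulatory
networks (no scale-free topology, no criticality tuning), so passing them
certifies the discrete-dynamics machinery, not biological realism.

## Problem sizes and runtime

The full perturbation suite (16 scenarios × 2 input values on 26 nodes)
completes in under two seconds on one CPU; the solver-equivalence ensembles
use 200–210 networks with n ∈ {4..12}, k ∈ {1..3}, chosen so exhaustive
enumeration stays a practical oracle while covering all three rule schemes.

## Limitations

Binary activity levels and synchronous updates cannot resolve expression
magnitudes, kinetics or transient order of events; conclusions are
qualitative fate structure only. The model covers the G1/S checkpoint only
(no G2/M arm), omits lncRNA sponging interactions, and treats DNA damage as
a constant environment rather than a decaying signal. Cyclic attractors of
the 26-node model are not enumerated (the fixed-point claims do not depend
on them, and the full STG at 2^26 states is out of scope for the
enumerative cycle finder).
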