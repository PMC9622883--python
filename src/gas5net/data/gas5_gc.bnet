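# lncRNA-GAS5 G1/S-checkpoint Boolean model, gastric-cancer context.
# 26 nodes, 73 regulator->target interactions. One synchronous update rule
# per node; & = AND, | = OR, ! = NOT. Each rule is annotated with the
# biological reading it encodes.
#
# Input: DNA_damage (self-sustaining, so each input value closes its own
# dynamics). Outputs: Proliferation, CellCycleArrest, Apoptosis.
targets, factors

# Double-strand breaks: free input held at whichever value the run fixes.
DNA_damage, DNA_damage

# ATM autophosphorylates upon double-strand breaks.
ATM, DNA_damage

# p38 MAPK is activated downstream of ATM in the damage response.
p38MAPK, ATM

# lncRNA GAS5 is induced by DNA damage.
GAS5, DNA_damage

# E2F1: driven by Myc, held off by unphosphorylated RB1, and silenced by
# GAS5 when the ATM/p38 MAPK signal is active (GAS5 acts on cell fate in a
# p38-dependent manner: with p38 knocked down, E2F1 stays on despite GAS5).
E2F1, Myc & !RB1 & !(GAS5 & p38MAPK)

# miR-34c: induced by the GAS5-licensed ATM/p38 MAPK pathway and
# transcriptionally repressed by E2F1 (relief of this repression is the
# indirect GAS5 -> E2F1 -| miR-34c route).
miR34c, GAS5 & ATM & p38MAPK & !E2F1

# Myc: constitutively expressed in the tumour context unless silenced by
# its direct targeting miRNA.
Myc, !miR34c

# HDAC1: tumour-promoting deacetylase, a direct miR-34c target.
HDAC1, !miR34c

# Sirt1: p53 deacetylase (keeps p53 inactive), a direct miR-34c target.
Sirt1, !miR34c

# Mdm2: basal expression plus p53-driven feedback; destabilized by ATM
# signalling and a direct miR-34c target.
Mdm2, (p53_A | !miR34c) & !ATM

# p53: stabilized by GAS5 and by ATM signalling, degraded by Mdm2.
p53, (GAS5 | ATM) & !Mdm2

# p53-A: arrester form (Ser-15/20 phosphorylation by ATM); excluded by the
# killer form and blocked by the deacetylases Sirt1/HDAC1.
p53_A, p53 & ATM & !p53_K & !Sirt1 & !HDAC1

# p53-K: killer form (Ser-46 phosphorylation via p38 MAPK), requires
# p53-INP1, is reverted by the phosphatase Wip1 and blocked by Sirt1.
# The A/K pair with Wip1/p53-INP1 forms the bistable arrest/apoptosis switch.
p53_K, p53 & p38MAPK & p53INP1 & !Wip1 & !Sirt1

# Wip1: transactivated by arrester p53.
Wip1, p53_A

# p53-INP1: p53 target gene sustaining Ser-46 phosphorylation.
p53INP1, p53 | p53_K

# p21: transactivated by arrester p53 or, p53-independently, by p38 MAPK
# signalling; repressed by HDAC1, shut off in killer-p53 mode and cleaved
# by active caspase (the p21/caspase mutual inhibition keeps the
# arrest-vs-apoptosis decision p53-independent).
p21, (p53_A | (p38MAPK & !Caspase)) & !HDAC1 & !p53_K

# Cdc25A: E2F1/Myc target phosphatase; degraded upon p53 arrest signalling
# and a direct miR-34c target.
Cdc25A, (E2F1 | Myc) & !miR34c & !p53_A

# cdk4/6-CycD: G1 kinase complex driven by E2F1/Myc and Cdc25A, inhibited
# by p21 and a direct miR-34c target (Cyclin D1 is part of this complex).
CDK46_CycD, (E2F1 | Myc) & Cdc25A & !miR34c & !p21

# cdk2/CycE: G1/S kinase complex, same control logic as cdk4/6-CycD.
CDK2_CycE, (E2F1 | Myc) & Cdc25A & !miR34c & !p21

# RB1: active (hypophosphorylated) only when the G1 kinase complexes are off.
RB1, !CDK46_CycD & !CDK2_CycE

# Bcl2: anti-apoptotic guard, a direct miR-34c target, repressed in
# killer-p53 mode.
Bcl2, !miR34c & !p53_K

# Bax: pro-apoptotic effector (carries the PUMA/BAX arm), induced by ATM
# and by p53, antagonized by Bcl2.
Bax, (ATM | p53_A | p53_K) & !Bcl2

# Caspase: executioner; needs Bax with Bcl2 gone, and is inhibited by p21
# (the switch that routes damage to arrest instead of death).
Caspase, Bax & !Bcl2 & !p21

# Phenotype readouts.
Proliferation, Myc & CDK46_CycD & CDK2_CycE & Cdc25A
CellCycleArrest, (p21 | RB1) & !Caspase
Apoptosis, Caspase & !Bcl2
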