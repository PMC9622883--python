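node	display_name	role
DNA_damage	DNA damage	input
ATM	ATM	regulator
p38MAPK	p38 MAPK	regulator
GAS5	lncRNA-GAS5	regulator
E2F1	E2F1	regulator
miR34c	miR-34c	regulator
Myc	Myc	regulator
HDAC1	HDAC1	regulator
Sirt1	Sirt1	regulator
Mdm2	Mdm2	regulator
p53	p53	regulator
p53_A	p53-A	regulator
p53_K	p53-K	regulator
Wip1	Wip1	regulator
p53INP1	p53-INP1	regulator
p21	p21	regulator
Cdc25A	Cdc25A	regulator
CDK46_CycD	cdk4/6-CycD	regulator
CDK2_CycE	cdk2/CycE	regulator
RB1	RB1	regulator
Bcl2	Bcl2	regulator
Bax	Bax	regulator
Caspase	caspase	regulator
Proliferation	Proliferation	output
CellCycleArrest	Cell cycle arrest	output
Apoptosis	Apoptosis	output
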