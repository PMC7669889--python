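# Transformed standard reaction Gibbs energies for the core-metabolism fixture.
# Vendored component-contribution (eQuilibrator-style) values, pH 7.5, I = 0.25 M,
# T = 298.15 K, forward direction as written in the fixture reaction table.
# GND is the thermodynamic keystone: its value makes the 1 mM / 200 mbar CO2
# transformed energy of the oxidative decarboxylation come out at about -1.5 kJ/mol.
# RPI carries exactly -RT*ln(0.458), the pentose-isomerase equilibrium constant
# used in the kinetic assay design.
id	dg0_prime_kj_mol	note
HEX1	-17.5	glucokinase
PGI	2.5	phosphoglucose isomerase
PFK	-16.1	phosphofructokinase
FBP	-11.3	fructose-1,6-bisphosphatase
FBA	21.5	FBP aldolase (cleavage direction)
TPI	5.5	triose-phosphate isomerase (DHAP->GAP)
GAPD	7.0	GAP dehydrogenase (phosphorylating)
PGK	-18.9	phosphoglycerate kinase (1,3-BPG->3PG)
PGM	4.2	phosphoglycerate mutase (3PG->2PG)
ENO	-4.0	enolase
PYK	-27.2	pyruvate kinase
PPS	-2.9	PEP synthetase (ATP->AMP)
ZWF	-4.0	glucose-6-phosphate dehydrogenase
PGL	-25.0	6-phosphogluconolactonase (irreversible within physiological range)
GND	10.9	6-phosphogluconate dehydrogenase (oxidative decarboxylation)
RPI	1.936	ribose-5-phosphate isomerase (R5P->Ru5P), -RT ln 0.458
RPE	-3.4	ribulose-phosphate 3-epimerase (Ru5P->Xu5P)
TKT1	3.0	transketolase (R5P+Xu5P->GAP+S7P)
TALA	-0.7	transaldolase (GAP+S7P->E4P+F6P)
TKT2	-10.0	transketolase (E4P+Xu5P->F6P+GAP)
EDD	-42.4	6-phosphogluconate dehydratase
EDA	16.3	KDPG aldolase (cleavage direction)
XYLI	4.3	xylose isomerase
XYLK	-17.0	xylulokinase
RBK	-17.5	ribokinase
LDH_D	-23.7	D-lactate dehydrogenase (pyruvate reduction)
PDH	-38.0	pyruvate dehydrogenase
PFL	-18.4	pyruvate formate lyase
PTAr	9.0	phosphotransacetylase
ACKr	-13.0	acetate kinase (acetyl-P->acetate)
ACALD	-17.5	acetaldehyde dehydrogenase (acylating)
ALCD2x	21.5	alcohol dehydrogenase (ethanol oxidation)
STHD	0.0	soluble-type transhydrogenase (fixture simplification)
ADK1	-0.3	adenylate kinase
ATPM	-29.6	ATP maintenance hydrolysis
OXPHOS	-160.0	lumped NADH oxidative phosphorylation, P/O = 2 (fixture)
H2DH	-18.1	hydrogen dehydrogenase (H2 + NAD+)
PRK	-16.0	phosphoribulokinase
RBPC	-31.8	ribulose-bisphosphate carboxylase
CS	-35.0	citrate synthase
ACONT	8.5	aconitase (lumped)
ICDHyr	5.0	isocitrate dehydrogenase (NADP)
AKGDH	-27.5	2-oxoglutarate dehydrogenase
SUCOAS	-1.0	succinyl-CoA synthetase (succinyl-CoA->succinate)
SUCD	18.0	succinate dehydrogenase (NAD-lumped, fixture)
FUM	-3.4	fumarase (fumarate->malate)
MDH	29.7	malate dehydrogenase (malate->OAA)
PPC	-40.0	PEP carboxylase
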