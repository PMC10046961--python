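# Per-drug peak-number call in each culture format: direction of the significant
# change (up / down) at the printed concentration, or "none" when no concentration
# reached significance versus same-plate vehicle.
drug	culture	direction	concentration_uM
Aspirin	2D	none	100
Aspirin	3D	none	100
Amoxicillin	2D	none	3
Amoxicillin	3D	none	3
Acetaminophen	2D	none	10
Acetaminophen	3D	none	10
Bicuculline	2D	none	10
Bicuculline	3D	none	10
Enoxacin	2D	none	10
Enoxacin	3D	none	10
GABA	2D	down	1
GABA	3D	none	3
Cyclothiazide	2D	up	10
Cyclothiazide	3D	up	10
Kainic Acid	2D	down	3
Kainic Acid	3D	up	3
Dizocilpine (MK-801)	2D	down	0.1
Dizocilpine (MK-801)	3D	down	0.1
Glutamate	2D	down	1
Glutamate	3D	none	30
Theophylline	2D	up	30
Theophylline	3D	up	30
Mefloquine	2D	down	1
Mefloquine	3D	none	30
Maprotiline	2D	down	3
Maprotiline	3D	none	10
Bupropion	2D	none	10
Bupropion	3D	none	10
Clozapine	2D	none	1
Clozapine	3D	none	1
Chlorpromazine	2D	down	0.3
Chlorpromazine	3D	none	3
Amoxapine	2D	down	3
Amoxapine	3D	none	3
Serotonin	2D	down	3
Serotonin	3D	down	3
Acetylcholine	2D	down	30
Acetylcholine	3D	down	30
Pilocarpine	2D	up	3
Pilocarpine	3D	none	10
4-Aminopyridine	2D	up	1
4-Aminopyridine	3D	up	1
Phenytoin	2D	down	3
Phenytoin	3D	none	100
Carbamazepine	2D	down	30
Carbamazepine	3D	none	100
Quinacrine	2D	down	10
Quinacrine	3D	none	10
Pazopanib	2D	none	10
Pazopanib	3D	none	10
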