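# Reference drug panel: identity, free therapeutic plasma concentration (µM),
# the four tested concentrations (µM), and the clinical activity label.
# "na" = value not available. The DMSO row is the vehicle entry (no doses).
name	cas	source	free_cmax_low	free_cmax_high	conc_1	conc_2	conc_3	conc_4	clinical_class	class_note
DMSO	-	Sigma	na	na	na	na	na	na	vehicle	Vehicle (0.1% DMSO)
Aspirin	50-78-2	Sigma	0.04	0.16	3.7	11.11	33.33	100	negative_control	Negative control
Amoxicillin	26787-78-0	Sigma	0.003	32	0.11	0.33	1	3	negative_control	Negative control
Acetaminophen	103-90-2	Sigma	0.46	0.46	1.11	3.33	10	30	negative_control	Negative control
Acetylcholine	66-23-9	Sigma	1	10	11.11	33.33	100	300	neuronally_active	Acetylcholine receptor agonist
Serotonin	153-98-0	Tocris Biosciences	1	2	3.7	11.11	33.33	100	neuronally_active	5HTR agonist
Bicuculline	485-49-4	Sigma	na	na	0.37	1.11	3.33	10	neuronally_active	GABAA receptor antagonist
Glutamate	56-86-0	Sigma	1	2	1.11	3.33	10	30	neuronally_active	Glutamate receptor agonist
Enoxacin	74011-58-8	Sigma	1	4	0.37	1.11	3.33	10	neuronally_active	Antibiotic
Cyclothiazide	2259-96-3	Sigma	30	30	3.7	11.11	33.33	100	neuronally_active	AMPA PAM
Theophylline	58-55-9	Sigma	8	15	11.11	33.33	100	300	neuronally_active	Adenosine receptor antagonist
Maprotiline	10262-69-8	Sigma	0.06	0.06	0.37	1.11	3.33	10	neuronally_active	Norepinephrine reuptake inhibitor
Bupropion	31677-93-7	Sigma	0.07	0.07	0.37	1.11	3.33	10	neuronally_active	Norepinephrine-dopamine reuptake inhibitor
Clozapine	5786-21-0	Sequoia research products Ltd.	0.3	0.3	0.04	0.11	0.33	1	neuronally_active	D2/5-HT2A antagonist
4-Aminopyridine	504-24-5	Sigma	0.025	0.075	0.37	1.11	3.33	10	neuronally_active	KCNA1 antagonist
Amoxapine	14028-44-5	Sigma	0.04	0.6	0.11	0.33	1	3	neuronally_active	Reuptake of norepinephrine and serotonin inhibitor
Pilocarpine	54-71-7	Sigma	0.03	0.55	0.37	1.11	3.33	10	neuronally_active	Muscarinic acetylcholine receptor agonist
Chlorpromazine	69-09-0	Sigma	0.05	0.15	0.11	0.33	1	3	neuronally_active	Dopamine/5HTR receptor antagonist
Pazopanib	444731-52-6	Sigma	0.6	1.2	0.37	1.11	3.33	10	neuronally_active	Tyrosine kinase inhibitor
Phenytoin	57-41-0	Sigma	4	15	3.7	11.11	33.33	100	neuronally_active	Sodium channel SCN1A antagonist
Dizocilpine (MK-801)	77086-21-6	Sequoia research products Ltd.	na	na	0.11	0.33	1	3	neuronally_active	NMDA antagonist
Mefloquine	51773-92-3	Sigma	0.095	0.095	1.11	3.33	10	30	neuronally_active	Adenosine receptor A2a/Connexin43 antagonist
Quinacrine	69-05-6	Sigma	0.05	0.05	0.37	1.11	3.33	10	neuronally_active	Phospholipase A2 inhibitor
Carbamazepine	298-46-4	Sigma	10	10	3.7	11.11	33.33	100	neuronally_active	Sodium channel antagonist
GABA	56-12-2	Sigma	1	1	0.11	0.33	1	3	neuronally_active	GABA receptor agonist
Kainic Acid	487-79-6	Sigma	na	na	0.37	1.11	3.33	10	neuronally_active	AMPA/NMDA/Glutamate receptor agonist
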