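# Per-drug, per-concentration mean and SD of the percent change in peak number
# from the same-well baseline window, with the rank-test significance versus
# same-plate vehicle (ns, p<0.05, p<0.01). 25 drugs x 2 cultures x 4 doses.
drug	culture	dose_index	concentration_uM	mean_delta_pct	sd_delta_pct	significance
4-Aminopyridine	2D	1	0.37	9.0	22.2	ns
4-Aminopyridine	2D	2	1.11	70.3	29.6	p<0.01
4-Aminopyridine	2D	3	3.33	85.8	76.0	p<0.01
4-Aminopyridine	2D	4	10	110.0	69.0	p<0.01
4-Aminopyridine	3D	1	0.37	16.7	9.1	ns
4-Aminopyridine	3D	2	1.11	62.4	69.9	p<0.05
4-Aminopyridine	3D	3	3.33	24.1	20.7	p<0.05
4-Aminopyridine	3D	4	10	89.0	27.1	p<0.01
Acetylcholine	2D	1	11.11	2.4	26.9	ns
Acetylcholine	2D	2	33.33	-31.5	51.8	ns
Acetylcholine	2D	3	100	-47.2	38.9	p<0.05
Acetylcholine	2D	4	300	-63.5	19.9	p<0.01
Acetylcholine	3D	1	11.11	-33.8	23.9	ns
Acetylcholine	3D	2	33.33	-51.6	20.6	p<0.05
Acetylcholine	3D	3	100	-34.9	38.3	ns
Acetylcholine	3D	4	300	-68.3	19.1	p<0.01
Amoxapine	2D	1	0.11	-5.2	8.5	ns
Amoxapine	2D	2	0.33	25.3	51.8	ns
Amoxapine	2D	3	1	12.5	27.9	ns
Amoxapine	2D	4	3	-35.3	14.8	p<0.05
Amoxapine	3D	1	0.11	-10.1	16.0	ns
Amoxapine	3D	2	0.33	-2.2	17.8	ns
Amoxapine	3D	3	1	-10.8	18.4	ns
Amoxapine	3D	4	3	-7.5	22.9	ns
Amoxicillin	2D	1	0.11	-10.5	29.7	ns
Amoxicillin	2D	2	0.33	8.3	38.2	ns
Amoxicillin	2D	3	1	27.2	7.9	p<0.05
Amoxicillin	2D	4	3	16.2	42.7	ns
Amoxicillin	3D	1	0.11	-8.0	8.8	ns
Amoxicillin	3D	2	0.33	1.4	17.2	ns
Amoxicillin	3D	3	1	9.3	35.0	ns
Amoxicillin	3D	4	3	18.3	28.6	ns
Aspirin	2D	1	3.7	-10.2	14.5	ns
Aspirin	2D	2	11.11	17.6	21.1	ns
Aspirin	2D	3	33.33	10.1	32.9	ns
Aspirin	2D	4	100	27.9	35.6	p<0.05
Aspirin	3D	1	3.7	-0.4	11.4	ns
Aspirin	3D	2	11.11	0.0	16.9	ns
Aspirin	3D	3	33.33	10.0	32.5	ns
Aspirin	3D	4	100	-8.2	17.6	ns
Bicuculline	2D	1	0.37	-29.4	33.4	ns
Bicuculline	2D	2	1.11	-3.5	30.0	ns
Bicuculline	2D	3	3.33	9.9	60.8	ns
Bicuculline	2D	4	10	5.8	53.6	ns
Bicuculline	3D	1	0.37	-14.9	23.0	ns
Bicuculline	3D	2	1.11	-13.0	23.0	ns
Bicuculline	3D	3	3.33	5.8	35.2	ns
Bicuculline	3D	4	10	-5.8	31.1	ns
Bupropion	2D	1	0.37	12.7	16.6	ns
Bupropion	2D	2	1.11	6.6	34.9	ns
Bupropion	2D	3	3.33	-12.0	17.9	ns
Bupropion	2D	4	10	6.0	41.8	ns
Bupropion	3D	1	0.37	1.3	28.1	ns
Bupropion	3D	2	1.11	-8.4	9.1	ns
Bupropion	3D	3	3.33	-2.2	13.6	ns
Bupropion	3D	4	10	12.5	46.0	ns
Carbamazepine	2D	1	3.7	-15.3	41.7	ns
Carbamazepine	2D	2	11.11	-17.0	21.0	ns
Carbamazepine	2D	3	33.33	-76.8	27.3	p<0.01
Carbamazepine	2D	4	100	-100.0	0.0	p<0.01
Carbamazepine	3D	1	3.7	11.4	12.9	ns
Carbamazepine	3D	2	11.11	3.9	24.7	ns
Carbamazepine	3D	3	33.33	-19.3	19.6	ns
Carbamazepine	3D	4	100	-21.5	40.8	ns
Chlorpromazine	2D	1	0.11	-27.0	19.3	ns
Chlorpromazine	2D	2	0.33	-29.5	6.7	ns
Chlorpromazine	2D	3	1	-59.8	12.9	p<0.01
Chlorpromazine	2D	4	3	-100.0	0.0	p<0.01
Chlorpromazine	3D	1	0.11	6.5	32.0	ns
Chlorpromazine	3D	2	0.33	-2.6	23.2	ns
Chlorpromazine	3D	3	1	11.5	32.3	ns
Chlorpromazine	3D	4	3	-4.8	15.4	ns
Clozapine	2D	1	0.04	15.3	50.6	ns
Clozapine	2D	2	0.11	24.2	24.9	p<0.05
Clozapine	2D	3	0.33	-15.0	32.3	ns
Clozapine	2D	4	1	-8.3	43.3	ns
Clozapine	3D	1	0.04	11.1	17.2	ns
Clozapine	3D	2	0.11	-10.0	14.9	ns
Clozapine	3D	3	0.33	-2.8	17.2	ns
Clozapine	3D	4	1	-13.9	16.4	ns
Cyclothiazide	2D	1	3.7	2.7	30.9	ns
Cyclothiazide	2D	2	11.11	178.3	116.3	p<0.01
Cyclothiazide	2D	3	33.33	-25.2	30.7	ns
Cyclothiazide	2D	4	100	-82.0	33.4	p<0.05
Cyclothiazide	3D	1	3.7	0.0	27.6	ns
Cyclothiazide	3D	2	11.11	21.5	33.0	ns
Cyclothiazide	3D	3	33.33	63.6	50.0	p<0.05
Cyclothiazide	3D	4	100	102.9	50.5	p<0.01
Enoxacin	2D	1	0.37	1.3	26.3	ns
Enoxacin	2D	2	1.11	2.3	32.6	ns
Enoxacin	2D	3	3.33	5.5	22.6	ns
Enoxacin	2D	4	10	2.0	17.3	ns
Enoxacin	3D	1	0.37	-16.9	25.0	ns
Enoxacin	3D	2	1.11	5.5	14.7	ns
Enoxacin	3D	3	3.33	13.2	21.3	ns
Enoxacin	3D	4	10	2.2	21.2	ns
GABA	2D	1	0.11	-1.6	27.3	ns
GABA	2D	2	0.33	-4.4	34.6	ns
GABA	2D	3	1	-12.4	51.3	ns
GABA	2D	4	3	-36.5	34.7	p<0.05
GABA	3D	1	0.11	5.0	23.4	ns
GABA	3D	2	0.33	-1.8	19.9	ns
GABA	3D	3	1	-0.6	28.3	ns
GABA	3D	4	3	2.2	24.8	ns
Glutamate	2D	1	1.11	-9.3	60.3	ns
Glutamate	2D	2	3.33	-8.9	68.5	p<0.05
Glutamate	2D	3	10	-60.3	49.9	p<0.05
Glutamate	2D	4	30	-100.0	0.0	p<0.05
Glutamate	3D	1	1.11	-7.0	20.1	ns
Glutamate	3D	2	3.33	12.3	33.6	ns
Glutamate	3D	3	10	20.0	34.4	ns
Glutamate	3D	4	30	8.4	17.3	ns
Kainic Acid	2D	1	0.37	21.0	42.1	ns
Kainic Acid	2D	2	1.11	26.8	13.7	p<0.05
Kainic Acid	2D	3	3.33	-53.3	43.8	ns
Kainic Acid	2D	4	10	-100.0	0.0	p<0.01
Kainic Acid	3D	1	0.37	1.3	36.9	ns
Kainic Acid	3D	2	1.11	16.4	15.3	ns
Kainic Acid	3D	3	3.33	18.7	19.7	p<0.05
Kainic Acid	3D	4	10	102.8	62.2	p<0.01
Maprotiline	2D	1	0.37	-0.7	18.1	ns
Maprotiline	2D	2	1.11	0.5	39.7	ns
Maprotiline	2D	3	3.33	-100.0	0.0	p<0.01
Maprotiline	2D	4	10	-100.0	0.0	p<0.01
Maprotiline	3D	1	0.37	-16.5	18.4	ns
Maprotiline	3D	2	1.11	-8.2	15.9	ns
Maprotiline	3D	3	3.33	-7.9	15.5	ns
Maprotiline	3D	4	10	1.9	21.9	ns
Mefloquine	2D	1	1.11	-30.8	21.7	ns
Mefloquine	2D	2	3.33	16.2	60.2	ns
Mefloquine	2D	3	10	-100.0	0.0	p<0.01
Mefloquine	2D	4	30	-100.0	0.0	p<0.01
Mefloquine	3D	1	1.11	2.8	21.5	ns
Mefloquine	3D	2	3.33	-11.1	9.1	ns
Mefloquine	3D	3	10	7.2	19.8	ns
Mefloquine	3D	4	30	-3.7	26.5	ns
Dizocilpine (MK-801)	2D	1	0.11	-82.8	10.9	p<0.01
Dizocilpine (MK-801)	2D	2	0.33	-90.4	9.3	p<0.01
Dizocilpine (MK-801)	2D	3	1	-84.6	17.7	p<0.01
Dizocilpine (MK-801)	2D	4	3	-96.3	5.7	p<0.01
Dizocilpine (MK-801)	3D	1	0.11	-49.1	16.7	p<0.05
Dizocilpine (MK-801)	3D	2	0.33	-67.3	24.4	p<0.01
Dizocilpine (MK-801)	3D	3	1	-97.2	6.8	p<0.01
Dizocilpine (MK-801)	3D	4	3	-84.8	9.4	p<0.01
Acetaminophen	2D	1	1.11	-11.7	20.4	ns
Acetaminophen	2D	2	3.33	-25.0	32.0	ns
Acetaminophen	2D	3	10	-18.2	56.4	ns
Acetaminophen	2D	4	30	-94.5	13.5	p<0.01
Acetaminophen	3D	1	1.11	2.2	37.2	ns
Acetaminophen	3D	2	3.33	-3.0	22.0	ns
Acetaminophen	3D	3	10	12.5	24.6	ns
Acetaminophen	3D	4	30	47.2	42.4	p<0.05
Pazopanib	2D	1	0.37	-49.0	31.8	ns
Pazopanib	2D	2	1.11	4.4	27.5	ns
Pazopanib	2D	3	3.33	11.3	60.3	ns
Pazopanib	2D	4	10	10.0	54.1	ns
Pazopanib	3D	1	0.37	6.4	38.1	ns
Pazopanib	3D	2	1.11	-4.2	10.2	ns
Pazopanib	3D	3	3.33	0.8	26.5	ns
Pazopanib	3D	4	10	-2.0	36.4	ns
Phenytoin	2D	1	3.7	-33.5	9.0	ns
Phenytoin	2D	2	11.11	-15.2	14.9	ns
Phenytoin	2D	3	33.33	-51.2	8.2	p<0.01
Phenytoin	2D	4	100	-27.5	14.4	ns
Phenytoin	3D	1	3.7	1.4	18.4	ns
Phenytoin	3D	2	11.11	-11.8	9.4	ns
Phenytoin	3D	3	33.33	-14.6	11.9	ns
Phenytoin	3D	4	100	-9.9	11.3	ns
Pilocarpine	2D	1	0.37	11.5	18.4	ns
Pilocarpine	2D	2	1.11	8.3	36.2	ns
Pilocarpine	2D	3	3.33	34.3	41.0	p<0.05
Pilocarpine	2D	4	10	-19.2	15.6	ns
Pilocarpine	3D	1	0.37	16.7	18.2	ns
Pilocarpine	3D	2	1.11	23.9	43.8	ns
Pilocarpine	3D	3	3.33	12.9	22.8	ns
Pilocarpine	3D	4	10	23.1	26.1	ns
Quinacrine	2D	1	0.37	-2.7	27.8	ns
Quinacrine	2D	2	1.11	-2.8	6.9	ns
Quinacrine	2D	3	3.33	-11.0	55.8	ns
Quinacrine	2D	4	10	-92.2	12.3	p<0.01
Quinacrine	3D	1	0.37	3.2	28.2	ns
Quinacrine	3D	2	1.11	0.4	37.4	ns
Quinacrine	3D	3	3.33	14.1	12.7	ns
Quinacrine	3D	4	10	12.5	14.7	ns
Serotonin	2D	1	3.7	-23.4	31.7	ns
Serotonin	2D	2	11.11	-1.7	74.7	ns
Serotonin	2D	3	33.33	-43.8	39.3	ns
Serotonin	2D	4	100	-45.8	22.5	p<0.01
Serotonin	3D	1	3.7	-70.7	32.7	p<0.01
Serotonin	3D	2	11.11	-69.1	29.8	p<0.01
Serotonin	3D	3	33.33	-82.1	16.6	p<0.01
Serotonin	3D	4	100	-80.3	29.4	p<0.01
Theophylline	2D	1	11.11	-5.7	22.7	ns
Theophylline	2D	2	33.33	24.7	43.3	ns
Theophylline	2D	3	100	39.3	23.5	p<0.05
Theophylline	2D	4	300	118.4	105.4	p<0.01
Theophylline	3D	1	11.11	2.0	14.7	ns
Theophylline	3D	2	33.33	53.5	60.4	p<0.05
Theophylline	3D	3	100	78.1	80.0	p<0.05
Theophylline	3D	4	300	114.2	98.1	p<0.05
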