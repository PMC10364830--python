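group	label	n_unweighted	weighted_pct	self_est	self_lo	self_hi	corrected_est	corrected_lo	corrected_hi
overall	Overall	344087	100	5.3	5.1	5.4	8.8	8.6	9.0
sex	Men	164001	50.5	4.2	4.0	4.5	6.5	6.2	6.8
sex	Women	180086	49.5	6.3	6.1	6.6	11.1	10.8	11.5
age	18-34	59991	29.6	4.6	4.3	4.9	9.5	9.0	10.1
age	35-49	66676	22.9	6.9	6.5	7.3	10.3	9.8	10.9
age	50-64	94700	25.1	6.2	5.7	6.6	10.0	9.5	10.5
age	65+	122720	22.4	3.5	3.2	3.7	4.9	4.6	5.2
race_ethnicity	Hispanic	26159	16.3	5.4	4.8	6.1	10.4	9.5	11.4
race_ethnicity	Non-Hispanic Asian	8130	5.5	1.3	0.9	2.1	2.3	1.7	3.3
race_ethnicity	Non-Hispanic Black	26435	12.0	9.6	8.7	10.4	14.6	13.7	15.5
race_ethnicity	Non-Hispanic White	266146	63.1	4.7	4.5	4.9	7.8	7.6	8.0
race_ethnicity	Other Non-Hispanic	17217	3.1	6.1	5.4	6.9	9.6	8.8	10.5
education	Less than high school graduate	21190	11.7	7.7	6.9	8.6	12.4	11.4	13.5
education	High school graduate or equivalent	91992	27.8	5.7	5.4	6.1	9.5	9.1	10.0
education	Some college	96233	31.2	5.7	5.4	6.1	9.6	9.2	10.1
education	College graduate	134105	29.3	3.4	3.2	3.5	5.8	5.5	6.0
marital_status	Married or domestic partnership	190904	55.2	4.7	4.5	4.9	7.9	7.6	8.2
marital_status	Not married	151906	44.8	6.0	5.7	6.3	9.8	9.5	10.2
employment	Employed	173685	55.9	5.1	4.8	5.3	8.6	8.3	8.9
employment	Unemployed	64907	24.3	6.9	6.5	7.4	11.9	11.3	12.5
employment	Retired	103483	19.8	3.8	3.5	4.2	5.6	5.2	6.0
census_region	Northeast	64515	16.6	4.3	4.0	4.6	7.1	6.7	7.5
census_region	Midwest	97988	21.0	5.9	5.6	6.1	10.0	9.6	10.4
census_region	South	100122	38.4	5.9	5.6	6.2	9.6	9.2	10.0
census_region	West	81462	24.0	4.5	4.0	5.0	7.6	7.0	8.3
census_division	New England	38543	4.5	4.0	3.6	4.3	6.6	6.1	7.0
census_division	Middle Atlantic	25972	12.2	4.4	4.0	4.8	7.3	6.8	7.8
census_division	East North Central	34376	14.4	6.0	5.6	6.4	10.3	9.7	10.8
census_division	West North Central	63612	6.6	5.6	5.4	5.9	9.3	9.0	9.7
census_division	South Atlantic	59068	20.4	5.4	5.0	5.8	8.6	8.1	9.1
census_division	East South Central	18501	6.1	7.3	6.7	7.8	12.0	11.3	12.7
census_division	West South Central	22553	11.9	6.0	5.4	6.6	10.2	9.4	11.1
census_division	Mountain	50992	7.6	4.3	4.0	4.6	7.3	6.9	7.7
census_division	Pacific	30470	16.4	4.6	3.9	5.3	7.8	6.9	8.8
locality	Metropolitan	236305	85.0	5.0	4.8	5.2	8.4	8.2	8.7
locality	Nonmetropolitan	107782	15.0	6.8	6.5	7.2	10.8	10.4	11.2
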