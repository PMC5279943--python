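# Baseline demographic, clinical and ECG characteristics of the two selected
# extreme-response arms (n = 10 per arm). Continuous rows carry mean and SD;
# the binary gender row carries counts. p_printed is an annotation.
variable	kind	low_mean	low_sd	high_mean	high_sd	p_printed
age_years	continuous	29.9	5.9	28.3	5.9	0.53
male_n	binary	8	.	1	.	0.006
bmi_kg_m2	continuous	23.6	0.9	22.9	2.7	0.40
sbp_mmhg	continuous	116.0	8.6	113.7	8.3	0.50
dbp_mmhg	continuous	72.2	4.8	68.0	4.2	0.07
resting_hr_bpm	continuous	59.6	5.9	63.2	8.4	0.37
pr_ms	continuous	166.7	24.7	143.5	18.1	0.09
qrs_ms	continuous	88.3	5.9	85.6	7.7	0.08
qtcf_ms	continuous	384.7	26.4	402.6	20.8	0.13
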