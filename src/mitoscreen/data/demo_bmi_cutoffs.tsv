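# DEMO-ONLY age/sex BMI percentile cutoffs (kg/m^2). These are fixture values
# for exercising the obesity classifier, not a national reference table.
# age band is [age_min, age_max); p85 = overweight, p95 = obese, p99 = severe.
sex	age_min	age_max	p85	p95	p99
M	5	12	19.0	21.0	24.0
M	12	18	21.0	23.5	26.5
M	18	120	24.0	28.0	32.0
F	5	12	19.5	21.5	24.5
F	12	18	21.5	24.0	27.0
F	18	120	24.0	28.0	32.0
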