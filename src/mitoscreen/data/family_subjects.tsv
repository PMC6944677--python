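# Anthropometrics of the affected matrilineal relatives (clinical summary
# table dialect). BMI as printed, 1 decimal; obese_duration in years,
# ">10.0" means more than ten.
id	age	sex	height_cm	weight_kg	bmi	obese_duration	carrier
III-1	9.3	M	154	60	25.3	4	1
II-2	38.2	F	165	70	25.7	>10.0	1
II-4	35.5	F	165	70	25.7	>10.0	1
III-2	6.3	M	128	40	24.4	1	1
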