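# Valid value ranges for pre-stroke measurements extracted from primary care.
# Out-of-range values are skipped (not truncated). Units: bmi kg/m2, sbp mmHg,
# egfr mL/min/1.73m2, hba1c mmol/mol, cholesterol mmol/L. Replaceable by users.
bmi: {min: 10, max: 80}
sbp: {min: 50, max: 300}
egfr: {min: 1, max: 250}
hba1c: {min: 15, max: 180}
total_cholesterol: {min: 0.5, max: 20}
hdl_cholesterol: {min: 0.1, max: 10}
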