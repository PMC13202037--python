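condition,coding_system,code
af_mi,snomed,49436004
af_mi,icd10,I48
af_mi,icd10,I21
af_mi,icd10,I22
diabetes,snomed,44054006
diabetes,icd10,E11
hypertension,snomed,38341003
hypertension,icd10,I10
ckd,snomed,709044004
ckd,icd10,N18
dementia,snomed,52448006
dementia,icd10,F00
dementia,icd10,F01
dementia,icd10,F03
cancer,snomed,363346000
cancer,icd10,C18
cancer,icd10,C34
cancer,icd10,C50
cancer,icd10,C61
copd,snomed,13645005
copd,icd10,J44
depression,snomed,35489007
depression,icd10,F32
depression,icd10,F33
dvt,snomed,128053003
dvt,icd10,I80
angina,snomed,194828000
angina,icd10,I20
obesity,snomed,414916001
obesity,icd10,E66
liver_disease,snomed,328383001
liver_disease,icd10,K70
liver_disease,icd10,K74
hypercholesterolaemia,snomed,13644009
arrhythmia,snomed,698247007
arrhythmia,icd10,I49
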