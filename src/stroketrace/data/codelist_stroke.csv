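coding_system,code,subtype
icd10,I63,ischaemic
icd10,I61,haemorrhagic
icd10,I64,unknown
snomed,422504002,ischaemic
snomed,274100004,haemorrhagic
snomed,230690007,unknown
ssnap_s2,infarction,ischaemic
ssnap_s2,haemorrhage,haemorrhagic
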