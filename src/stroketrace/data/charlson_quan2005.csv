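category,weight,icd10_prefix
mi,1,I21
mi,1,I22
mi,1,I252
chf,1,I099
chf,1,I110
chf,1,I130
chf,1,I132
chf,1,I255
chf,1,I420
chf,1,I425
chf,1,I426
chf,1,I427
chf,1,I428
chf,1,I429
chf,1,I43
chf,1,I50
chf,1,P290
pvd,1,I70
pvd,1,I71
pvd,1,I731
pvd,1,I738
pvd,1,I739
pvd,1,I771
pvd,1,I790
pvd,1,I792
pvd,1,K551
pvd,1,K558
pvd,1,K559
pvd,1,Z958
pvd,1,Z959
cvd,1,G45
cvd,1,G46
cvd,1,H340
cvd,1,I60
cvd,1,I61
cvd,1,I62
cvd,1,I63
cvd,1,I64
cvd,1,I65
cvd,1,I66
cvd,1,I67
cvd,1,I68
cvd,1,I69
dementia,1,F00
dementia,1,F01
dementia,1,F02
dementia,1,F03
dementia,1,F051
dementia,1,G30
dementia,1,G311
cpd,1,I278
cpd,1,I279
cpd,1,J40
cpd,1,J41
cpd,1,J42
cpd,1,J43
cpd,1,J44
cpd,1,J45
cpd,1,J46
cpd,1,J47
cpd,1,J60
cpd,1,J61
cpd,1,J62
cpd,1,J63
cpd,1,J64
cpd,1,J65
cpd,1,J66
cpd,1,J67
cpd,1,J684
cpd,1,J701
cpd,1,J703
rheum,1,M05
rheum,1,M06
rheum,1,M315
rheum,1,M32
rheum,1,M33
rheum,1,M34
rheum,1,M351
rheum,1,M353
rheum,1,M360
pud,1,K25
pud,1,K26
pud,1,K27
pud,1,K28
mild_liver,1,B18
mild_liver,1,K700
mild_liver,1,K701
mild_liver,1,K702
mild_liver,1,K703
mild_liver,1,K709
mild_liver,1,K713
mild_liver,1,K714
mild_liver,1,K715
mild_liver,1,K717
mild_liver,1,K73
mild_liver,1,K74
mild_liver,1,K760
mild_liver,1,K762
mild_liver,1,K763
mild_liver,1,K764
mild_liver,1,K768
mild_liver,1,K769
mild_liver,1,Z944
diabetes_uncomplicated,1,E100
diabetes_uncomplicated,1,E101
diabetes_uncomplicated,1,E106
diabetes_uncomplicated,1,E108
diabetes_uncomplicated,1,E109
diabetes_uncomplicated,1,E110
diabetes_uncomplicated,1,E111
diabetes_uncomplicated,1,E116
diabetes_uncomplicated,1,E118
diabetes_uncomplicated,1,E119
diabetes_uncomplicated,1,E120
diabetes_uncomplicated,1,E121
diabetes_uncomplicated,1,E126
diabetes_uncomplicated,1,E128
diabetes_uncomplicated,1,E129
diabetes_uncomplicated,1,E130
diabetes_uncomplicated,1,E131
diabetes_uncomplicated,1,E136
diabetes_uncomplicated,1,E138
diabetes_uncomplicated,1,E139
diabetes_uncomplicated,1,E140
diabetes_uncomplicated,1,E141
diabetes_uncomplicated,1,E146
diabetes_uncomplicated,1,E148
diabetes_uncomplicated,1,E149
diabetes_complicated,2,E102
diabetes_complicated,2,E103
diabetes_complicated,2,E104
diabetes_complicated,2,E105
diabetes_complicated,2,E107
diabetes_complicated,2,E112
diabetes_complicated,2,E113
diabetes_complicated,2,E114
diabetes_complicated,2,E115
diabetes_complicated,2,E117
diabetes_complicated,2,E122
diabetes_complicated,2,E123
diabetes_complicated,2,E124
diabetes_complicated,2,E125
diabetes_complicated,2,E127
diabetes_complicated,2,E132
diabetes_complicated,2,E133
diabetes_complicated,2,E134
diabetes_complicated,2,E135
diabetes_complicated,2,E137
diabetes_complicated,2,E142
diabetes_complicated,2,E143
diabetes_complicated,2,E144
diabetes_complicated,2,E145
diabetes_complicated,2,E147
hemiplegia,2,G041
hemiplegia,2,G114
hemiplegia,2,G801
hemiplegia,2,G802
hemiplegia,2,G81
hemiplegia,2,G82
hemiplegia,2,G830
hemiplegia,2,G831
hemiplegia,2,G832
hemiplegia,2,G833
hemiplegia,2,G834
hemiplegia,2,G839
renal,2,I120
renal,2,I131
renal,2,N032
renal,2,N033
renal,2,N034
renal,2,N035
renal,2,N036
renal,2,N037
renal,2,N052
renal,2,N053
renal,2,N054
renal,2,N055
renal,2,N056
renal,2,N057
renal,2,N18
renal,2,N19
renal,2,N250
renal,2,Z490
renal,2,Z491
renal,2,Z492
renal,2,Z940
renal,2,Z992
malignancy,2,C00
malignancy,2,C01
malignancy,2,C02
malignancy,2,C03
malignancy,2,C04
malignancy,2,C05
malignancy,2,C06
malignancy,2,C07
malignancy,2,C08
malignancy,2,C09
malignancy,2,C10
malignancy,2,C11
malignancy,2,C12
malignancy,2,C13
malignancy,2,C14
malignancy,2,C15
malignancy,2,C16
malignancy,2,C17
malignancy,2,C18
malignancy,2,C19
malignancy,2,C20
malignancy,2,C21
malignancy,2,C22
malignancy,2,C23
malignancy,2,C24
malignancy,2,C25
malignancy,2,C26
malignancy,2,C30
malignancy,2,C31
malignancy,2,C32
malignancy,2,C33
malignancy,2,C34
malignancy,2,C37
malignancy,2,C38
malignancy,2,C39
malignancy,2,C40
malignancy,2,C41
malignancy,2,C43
malignancy,2,C45
malignancy,2,C46
malignancy,2,C47
malignancy,2,C48
malignancy,2,C49
malignancy,2,C50
malignancy,2,C51
malignancy,2,C52
malignancy,2,C53
malignancy,2,C54
malignancy,2,C55
malignancy,2,C56
malignancy,2,C57
malignancy,2,C58
malignancy,2,C60
malignancy,2,C61
malignancy,2,C62
malignancy,2,C63
malignancy,2,C64
malignancy,2,C65
malignancy,2,C66
malignancy,2,C67
malignancy,2,C68
malignancy,2,C69
malignancy,2,C70
malignancy,2,C71
malignancy,2,C72
malignancy,2,C73
malignancy,2,C74
malignancy,2,C75
malignancy,2,C76
malignancy,2,C81
malignancy,2,C82
malignancy,2,C83
malignancy,2,C84
malignancy,2,C85
malignancy,2,C88
malignancy,2,C90
malignancy,2,C91
malignancy,2,C92
malignancy,2,C93
malignancy,2,C94
malignancy,2,C95
malignancy,2,C96
malignancy,2,C97
severe_liver,3,I850
severe_liver,3,I859
severe_liver,3,I864
severe_liver,3,I982
severe_liver,3,K704
severe_liver,3,K711
severe_liver,3,K721
severe_liver,3,K729
severe_liver,3,K765
severe_liver,3,K766
severe_liver,3,K767
metastatic,6,C77
metastatic,6,C78
metastatic,6,C79
metastatic,6,C80
hiv,6,B20
hiv,6,B21
hiv,6,B22
hiv,6,B24
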