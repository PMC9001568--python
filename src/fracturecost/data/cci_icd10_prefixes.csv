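prefix,category
I21,myocardial_infarction
I22,myocardial_infarction
I252,myocardial_infarction
I099,congestive_heart_failure
I110,congestive_heart_failure
I130,congestive_heart_failure
I132,congestive_heart_failure
I255,congestive_heart_failure
I420,congestive_heart_failure
I43,congestive_heart_failure
I50,congestive_heart_failure
I70,peripheral_vascular_disease
I71,peripheral_vascular_disease
I731,peripheral_vascular_disease
I739,peripheral_vascular_disease
G45,cerebrovascular_disease
G46,cerebrovascular_disease
I6,cerebrovascular_disease
F00,dementia
F01,dementia
F02,dementia
F03,dementia
G30,dementia
J40,chronic_pulmonary_disease
J41,chronic_pulmonary_disease
J42,chronic_pulmonary_disease
J43,chronic_pulmonary_disease
J44,chronic_pulmonary_disease
J45,chronic_pulmonary_disease
J46,chronic_pulmonary_disease
J47,chronic_pulmonary_disease
J60,chronic_pulmonary_disease
J61,chronic_pulmonary_disease
J62,chronic_pulmonary_disease
J63,chronic_pulmonary_disease
J64,chronic_pulmonary_disease
J65,chronic_pulmonary_disease
J66,chronic_pulmonary_disease
J67,chronic_pulmonary_disease
M05,rheumatic_disease
M06,rheumatic_disease
M315,rheumatic_disease
M32,rheumatic_disease
M33,rheumatic_disease
M34,rheumatic_disease
M351,rheumatic_disease
M353,rheumatic_disease
K25,peptic_ulcer_disease
K26,peptic_ulcer_disease
K27,peptic_ulcer_disease
K28,peptic_ulcer_disease
B18,mild_liver_disease
K70,mild_liver_disease
K713,mild_liver_disease
K73,mild_liver_disease
K74,mild_liver_disease
K760,mild_liver_disease
K762,mild_liver_disease
K763,mild_liver_disease
K764,mild_liver_disease
K768,mild_liver_disease
K769,mild_liver_disease
Z944,mild_liver_disease
E10,diabetes_without_complication
E11,diabetes_without_complication
E13,diabetes_without_complication
E14,diabetes_without_complication
E102,diabetes_with_complication
E103,diabetes_with_complication
E104,diabetes_with_complication
E105,diabetes_with_complication
E107,diabetes_with_complication
E112,diabetes_with_complication
E113,diabetes_with_complication
E114,diabetes_with_complication
E115,diabetes_with_complication
E117,diabetes_with_complication
E132,diabetes_with_complication
E133,diabetes_with_complication
E134,diabetes_with_complication
E135,diabetes_with_complication
E137,diabetes_with_complication
E142,diabetes_with_complication
E143,diabetes_with_complication
E144,diabetes_with_complication
E145,diabetes_with_complication
E147,diabetes_with_complication
G041,hemiplegia_paraplegia
G114,hemiplegia_paraplegia
G801,hemiplegia_paraplegia
G802,hemiplegia_paraplegia
G81,hemiplegia_paraplegia
G82,hemiplegia_paraplegia
G83,hemiplegia_paraplegia
I120,renal_disease
I131,renal_disease
N052,renal_disease
N053,renal_disease
N054,renal_disease
N055,renal_disease
N056,renal_disease
N057,renal_disease
N18,renal_disease
N19,renal_disease
N250,renal_disease
Z490,renal_disease
Z491,renal_disease
Z492,renal_disease
Z940,renal_disease
Z992,renal_disease
C,malignancy
C77,metastatic_solid_tumor
C78,metastatic_solid_tumor
C79,metastatic_solid_tumor
C80,metastatic_solid_tumor
K704,moderate_severe_liver_disease
K711,moderate_severe_liver_disease
K721,moderate_severe_liver_disease
K729,moderate_severe_liver_disease
K765,moderate_severe_liver_disease
K766,moderate_severe_liver_disease
K767,moderate_severe_liver_disease
I850,moderate_severe_liver_disease
I859,moderate_severe_liver_disease
I864,moderate_severe_liver_disease
I982,moderate_severe_liver_disease
B20,aids_hiv
B21,aids_hiv
B22,aids_hiv
B24,aids_hiv
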