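category,weight,hierarchy_group
myocardial_infarction,0,
congestive_heart_failure,2,
peripheral_vascular_disease,0,
cerebrovascular_disease,0,
dementia,2,
chronic_pulmonary_disease,1,
rheumatic_disease,1,
peptic_ulcer_disease,0,
mild_liver_disease,2,liver
diabetes_without_complication,0,diabetes
diabetes_with_complication,1,diabetes
hemiplegia_paraplegia,2,
renal_disease,1,
malignancy,2,cancer
moderate_severe_liver_disease,4,liver
metastatic_solid_tumor,6,cancer
aids_hiv,4,
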