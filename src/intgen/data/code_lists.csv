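code,system,disorder,source,definition
SR_DEPRESSION,interview-code,mood,interview,initial_self_report
SR_POSTNATAL_DEPRESSION,interview-code,mood,interview,initial_self_report
SR_ANXIETY_PANIC,interview-code,anxiety,interview,initial_self_report
SR_SCHIZOPHRENIA,interview-code,exclusion,interview,
SR_BIPOLAR,interview-code,exclusion,interview,
MED_SERTRALINE,med-code,mood,medication,medication_self_report
MED_FLUOXETINE,med-code,mood,medication,medication_self_report
MED_CITALOPRAM,med-code,mood,medication,medication_self_report
MED_AMITRIPTYLINE,med-code,mood,medication,medication_self_report
MED_SERTRALINE,med-code,anxiety,medication,medication_self_report
MED_FLUOXETINE,med-code,anxiety,medication,medication_self_report
MED_CITALOPRAM,med-code,anxiety,medication,medication_self_report
MED_AMITRIPTYLINE,med-code,anxiety,medication,medication_self_report
MED_DIAZEPAM,med-code,anxiety,medication,medication_self_report
MED_LORAZEPAM,med-code,anxiety,medication,medication_self_report
F32.0,icd10-like,mood,hospital,hospital
F32.1,icd10-like,mood,hospital,hospital
F32.9,icd10-like,mood,hospital,hospital
F33.0,icd10-like,mood,hospital,hospital
F33.1,icd10-like,mood,hospital,hospital
F40.0,icd10-like,anxiety,hospital,hospital
F41.0,icd10-like,anxiety,hospital,hospital
F41.1,icd10-like,anxiety,hospital,hospital
F41.9,icd10-like,anxiety,hospital,hospital
F20.0,icd10-like,exclusion,hospital,
F20.9,icd10-like,exclusion,hospital,
F31.0,icd10-like,exclusion,hospital,
F31.9,icd10-like,exclusion,hospital,
E112.,read-like,mood,primary_care,primary_care
E113.,read-like,mood,primary_care,primary_care
E2B0.,read-like,mood,primary_care,primary_care
E2B1.,read-like,mood,primary_care,primary_care
E200.,read-like,anxiety,primary_care,primary_care
E2000,read-like,anxiety,primary_care,primary_care
E202.,read-like,anxiety,primary_care,primary_care
EU20.,read-like,exclusion,primary_care,
E110.,read-like,exclusion,primary_care,
E111.,read-like,exclusion,primary_care,
MHQ_DEPRESSION,mhq-code,mood,mhq,mhq_self_report
MHQ_SOCIAL_ANXIETY,mhq-code,anxiety,mhq,mhq_self_report
MHQ_AGORAPHOBIA,mhq-code,anxiety,mhq,mhq_self_report
MHQ_PANIC_ATTACKS,mhq-code,anxiety,mhq,mhq_self_report
MHQ_ANXIETY,mhq-code,anxiety,mhq,mhq_self_report
MHQ_NERVES,mhq-code,anxiety,mhq,mhq_self_report
MHQ_GAD,mhq-code,anxiety,mhq,mhq_self_report
MHQ_SCHIZOPHRENIA,mhq-code,exclusion,mhq,
MHQ_BIPOLAR,mhq-code,exclusion,mhq,
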