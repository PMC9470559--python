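patient_id,term,grade,related
P01,hypertension,2,true
P02,hypertension,3,true
P03,hypertension,1,true
P04,hypertension,2,true
P05,hypertension,3,true
P06,hypertension,1,true
P07,hypertension,2,true
P08,hypertension,3,true
P09,hypertension,1,true
P10,hypertension,2,true
P11,hypertension,3,true
P12,hypertension,1,true
P13,hypertension,2,true
P14,hypertension,3,true
P15,hypertension,1,true
P16,hypertension,2,true
P17,hypertension,3,true
P18,hypertension,1,true
P19,hypertension,2,true
P20,hypertension,3,true
P01,fatigue,1,true
P05,fatigue,1,true
P08,fatigue,1,true
P09,fatigue,1,true
P12,fatigue,1,true
P13,fatigue,1,true
P14,fatigue,1,true
P15,fatigue,1,true
P16,fatigue,1,true
P17,fatigue,1,true
P18,fatigue,1,true
P19,fatigue,1,true
P20,fatigue,1,true
P02,proteinuria,1,true
P03,proteinuria,1,true
P06,proteinuria,1,true
P08,proteinuria,2,true
P10,proteinuria,1,true
P11,proteinuria,1,true
P12,proteinuria,1,true
P14,proteinuria,1,true
P17,proteinuria,2,true
P19,proteinuria,1,true
P04,mucositis,1,true
P07,mucositis,1,true
P09,mucositis,3,true
P13,mucositis,1,true
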