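patient_id,registered,received_dose,central_review_excluded,age,weight,sex,ecog,m_stage,mskcc_risk,serum_creatinine,creatinine_uln,biopsy_ccrcc,urinalysis_protein_plus
P01,true,true,false,49,70.0,male,0,M1,intermediate,0.8,1.2,true,0
P02,true,true,false,51,72.0,male,1,M0,,0.82,1.2,true,1
P03,true,true,false,53,74.0,male,0,M1,intermediate,0.84,1.2,true,0
P04,true,true,false,52,76.0,male,1,M0,,0.86,1.2,true,1
P05,true,true,false,54,78.0,male,0,M1,intermediate,0.88,1.2,true,0
P06,true,true,false,56,80.0,male,1,M0,,0.9,1.2,true,1
P07,true,true,false,55,82.0,male,0,M1,intermediate,0.92,1.2,true,0
P08,true,true,false,57,84.0,male,1,M0,,0.94,1.2,true,1
P09,true,true,false,59,86.0,male,0,M1,intermediate,0.96,1.2,true,0
P10,true,true,false,58,88.0,male,1,M0,,0.98,1.2,true,1
P11,true,true,false,60,90.0,male,0,M1,intermediate,1.0,1.2,true,0
P12,true,true,false,62,92.0,male,1,M0,,1.02,1.2,true,1
P13,true,true,false,61,94.0,male,0,M1,intermediate,1.04,1.2,true,0
P14,true,true,false,63,96.0,male,1,M0,,1.06,1.2,true,1
P15,true,true,false,65,98.0,male,0,M1,intermediate,1.08,1.2,true,0
P16,true,true,false,64,100.0,female,1,M0,,1.1,1.2,true,1
P17,true,true,false,66,102.0,female,0,M1,intermediate,1.12,1.2,true,0
P18,true,true,false,68,104.0,female,1,M0,,1.14,1.2,true,1
P19,true,true,false,67,106.0,female,0,M0,,1.16,1.2,true,0
P20,true,true,false,69,108.0,female,1,M0,,1.18,1.2,true,1
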