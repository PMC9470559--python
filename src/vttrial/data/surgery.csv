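patient_id,phase,approach,incision_rank,level_of_control,venovenous_bypass,hypothermic_cardiac_arrest,pringle
P01,planned,open,2,1,false,false,false
P01,performed,open,1,1,false,false,false
P02,planned,open,1,1,false,false,false
P02,performed,open,1,1,false,false,false
P03,planned,open,1,1,false,false,false
P03,performed,minimally_invasive,1,1,false,false,false
P04,planned,open,1,1,false,false,false
P04,performed,open,1,1,false,false,false
P05,planned,open,2,2,false,false,false
P05,performed,open,2,1,false,false,false
P06,planned,open,2,2,false,false,false
P06,performed,open,2,2,false,false,false
P07,planned,open,2,2,false,false,false
P07,performed,open,2,2,false,false,false
P08,planned,open,2,3,false,false,false
P08,performed,minimally_invasive,1,2,false,false,false
P09,planned,open,3,3,false,false,false
P09,performed,open,2,3,false,false,false
P10,planned,open,2,2,false,false,false
P10,performed,open,2,1,false,false,false
P12,planned,open,3,3,false,false,false
P12,performed,open,3,3,false,false,false
P13,planned,open,2,3,false,false,false
P13,performed,open,2,3,false,false,false
P14,planned,open,2,3,false,false,false
P14,performed,open,2,3,false,false,false
P15,planned,open,2,3,false,false,false
P15,performed,open,2,3,false,false,false
P16,planned,open,3,3,false,false,false
P16,performed,open,3,3,false,false,false
P17,planned,open,3,5,true,false,false
P17,performed,open,3,3,false,false,false
P18,planned,open,3,4,false,false,false
P18,performed,open,3,4,false,false,false
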