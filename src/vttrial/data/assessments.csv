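patient_id,timepoint,side,tip_landmark,tip_distance_mm,rv_mm,ivc_above_mm,ivc_below_mm,target_sum_mm,new_lesion
P01,baseline,left,RV_MAIN,,50.0,0.0,0.0,100.0,false
P01,week3,left,RV_MAIN,,40.0,0.0,0.0,95.0,false
P01,week9,left,RV_LATERAL_TO_GONADAL,,28.0,0.0,0.0,90.0,false
P02,baseline,right,RV_MAIN,,40.0,0.0,0.0,80.0,false
P02,week3,right,RV_MAIN,,36.0,0.0,0.0,78.0,false
P02,week9,right,RV_MAIN,,30.0,0.0,0.0,76.0,false
P03,baseline,left,RV_MAIN,,35.0,0.0,0.0,110.0,false
P03,week3,left,RV_MAIN,,34.0,0.0,0.0,108.0,false
P03,week9,left,RV_MAIN,,30.0,0.0,0.0,105.0,false
P04,baseline,right,RV_MAIN,,45.0,0.0,0.0,90.0,false
P04,week3,right,RV_MAIN,,45.0,0.0,0.0,90.0,false
P04,week9,right,RV_MAIN,,45.0,0.0,0.0,90.0,false
P05,baseline,right,IVC,12.0,40.0,12.0,8.0,120.0,false
P05,week3,right,IVC,8.0,35.0,8.0,6.0,118.0,false
P05,week9,right,RV_MAIN,,30.0,0.0,0.0,115.0,false
P06,baseline,left,IVC,15.0,30.0,15.0,5.0,70.0,false
P06,week3,left,IVC,14.0,29.0,14.0,5.0,70.0,false
P06,week9,left,IVC,13.0,28.0,13.0,4.0,69.0,false
P07,baseline,right,IVC,10.0,35.0,10.0,0.0,95.0,false
P07,week3,right,IVC,11.0,37.0,11.0,0.0,96.0,false
P07,week9,right,IVC,12.0,40.0,12.0,0.0,97.0,false
P08,baseline,left,IVC,45.0,50.0,45.0,15.0,130.0,false
P08,week3,left,IVC,30.0,40.0,30.0,12.0,120.0,false
P08,week9,left,IVC,15.0,30.0,15.0,9.0,88.0,false
P09,baseline,right,IVC,60.0,40.0,60.0,20.0,140.0,false
P09,week3,right,IVC,45.0,35.0,45.0,16.0,135.0,false
P09,week9,right,IVC,18.0,28.0,18.0,12.0,130.0,false
P10,baseline,left,IVC,30.0,45.0,30.0,10.0,100.0,false
P10,week3,left,IVC,24.0,40.0,24.0,8.0,98.0,false
P10,week9,left,IVC,10.0,35.0,10.0,6.0,96.0,false
P11,baseline,right,IVC,50.0,40.0,50.0,10.0,85.0,false
P11,week3,right,IVC,47.0,38.0,47.0,10.0,85.0,false
P11,week9,right,IVC,44.0,36.0,44.0,9.0,84.0,false
P12,baseline,left,IVC,70.0,55.0,70.0,25.0,150.0,false
P12,week3,left,IVC,66.0,52.0,66.0,24.0,148.0,false
P12,week9,left,IVC,62.0,50.0,62.0,22.0,146.0,false
P13,baseline,right,IVC,40.0,30.0,40.0,12.0,75.0,false
P13,week3,right,IVC,39.0,29.0,39.0,12.0,75.0,false
P13,week9,right,IVC,38.0,29.0,38.0,11.0,74.0,false
P14,baseline,left,IVC,55.0,45.0,55.0,18.0,105.0,false
P14,week3,left,IVC,53.0,44.0,53.0,17.0,104.0,false
P14,week9,left,IVC,52.0,43.0,52.0,17.0,103.0,false
P15,baseline,right,IVC,35.0,38.0,35.0,9.0,92.0,false
P15,week3,right,IVC,37.0,40.0,37.0,10.0,93.0,false
P15,week9,right,IVC,40.0,43.0,40.0,11.0,94.0,false
P16,baseline,left,IVC,65.0,48.0,65.0,22.0,125.0,false
P16,week3,left,IVC,67.0,49.0,67.0,23.0,126.0,true
P16,week9,left,IVC,72.0,52.0,72.0,26.0,128.0,true
P17,baseline,right,IVC_AT_OR_ABOVE_HEPATIC_BELOW_DIAPHRAGM,,55.0,120.0,25.0,160.0,false
P17,week3,right,IVC_AT_OR_ABOVE_HEPATIC_BELOW_DIAPHRAGM,,50.0,105.0,22.0,150.0,false
P17,week9,right,IVC,70.0,40.0,70.0,16.0,110.0,false
P18,baseline,left,IVC_AT_OR_ABOVE_HEPATIC_BELOW_DIAPHRAGM,,45.0,110.0,20.0,135.0,false
P18,week3,left,IVC_AT_OR_ABOVE_HEPATIC_BELOW_DIAPHRAGM,,44.0,106.0,20.0,134.0,false
P18,week9,left,IVC_AT_OR_ABOVE_HEPATIC_BELOW_DIAPHRAGM,,42.0,101.0,18.0,132.0,false
P19,baseline,right,IVC_ABOVE_DIAPHRAGM,,60.0,180.0,30.0,170.0,false
P19,week3,right,IVC_ABOVE_DIAPHRAGM,,55.0,160.0,27.0,165.0,false
P19,week9,right,IVC_AT_OR_ABOVE_HEPATIC_BELOW_DIAPHRAGM,,45.0,130.0,20.0,160.0,true
P20,baseline,left,IVC_ABOVE_DIAPHRAGM,,55.0,190.0,28.0,155.0,false
P20,week3,left,IVC_ABOVE_DIAPHRAGM,,60.0,205.0,32.0,158.0,false
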