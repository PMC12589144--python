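patient_id,conditions,ferritin_ugL,published_hscore,published_probability_band,clinician_hlh_diagnosis
T2-01,ESRD; AKI; ALI; renal transplant,9107,174,54,false
T2-02,Lung transplant; sepsis,>16500,174,54,false
T2-03,CLL; CMV,5150,177,54,false
T2-04,HLH; Sweet's syndrome,>16500,177,54,true
T2-05,Massive haemorrhage; DIC,>16500,181,70,false
T2-06,Myeloma,14349,193,80,false
T2-07,HLH; ALL,>16500,194,80,true
T2-08,ALL; sepsis,>16500,202,88,false
T2-09,AML; GVHD,>16500,205,88,false
T2-10,HLH; SLE; HSV,12273,227,96,true
T2-11,APML; multi-organ failure,>16500,241,99,false
T2-12,HLH; bilateral lung transplant,>16500,267,>99,true
T2-13,HLH; SLE; CMV,>16500,291,>99,true
T2-14,HLH; EBV,>16500,321,>99,true
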