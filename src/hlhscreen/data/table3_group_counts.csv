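label,definition,low_with,low_total,high_with,high_total,published_statistic,published_p,test_name
haemoglobin,haemoglobin < 90 g/L,38,106,12,14,12.6515,0.000375,chi-squared
platelets,platelets < 100e9/L,44,106,12,14,9.7093,0.001833,chi-squared
neutrophils,neutrophils < 1e9/L,12,106,8,14,18.6954,0.000015,chi-squared
fever,documented fever,37,106,12,14,13.214,0.000278,chi-squared
hepatomegaly,hepatomegaly,11,106,7,14,15.2275,0.000095,chi-squared
splenomegaly,splenomegaly,18,106,10,14,20.4939,0.00001,chi-squared
triglycerides,triglycerides > 1.5 mmol/L,6,106,10,14,46.2907,0.00001,chi-squared
fibrinogen,fibrinogen < 2.5 g/L,10,106,7,14,16.7361,0.000043,chi-squared
haemophagocytosis,haemophagocytosis recorded,1,106,3,14,16.1056,0.00006,chi-squared
immunosuppression,immunosuppression,31,106,12,14,17.1505,0.000035,chi-squared
transaminase,AST > 30 or ALT > 100 U/L,47,106,10,14,3.639,0.05644,chi-squared
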