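disease,sex,age_lo,age_hi,rr,lo95,hi95
colon_cancer,both,20,35,1.00,1.00,1.00
colon_cancer,both,35,100,1.03,1.01,1.05
breast_cancer,female,20,35,1.00,1.00,1.00
breast_cancer,female,35,100,1.03,1.02,1.04
endometrial_cancer,female,20,35,1.00,1.00,1.00
endometrial_cancer,female,35,100,1.10,1.07,1.14
kidney_cancer,both,20,35,1.00,1.00,1.00
kidney_cancer,both,35,100,1.06,1.03,1.08
osteoarthritis,both,20,35,1.00,1.00,1.00
osteoarthritis,both,35,100,1.04,1.03,1.06
ischemic_heart_disease,both,20,35,1.00,1.00,1.00
ischemic_heart_disease,both,35,45,1.12,1.05,1.19
ischemic_heart_disease,both,45,60,1.10,1.08,1.14
ischemic_heart_disease,both,60,70,1.06,1.03,1.08
ischemic_heart_disease,both,70,80,1.04,1.02,1.06
ischemic_heart_disease,both,80,100,1.02,1.00,1.05
hypertensive_heart_disease,both,20,45,1.00,1.00,1.00
hypertensive_heart_disease,both,45,60,1.09,1.03,1.14
hypertensive_heart_disease,both,60,70,1.16,1.05,1.27
hypertensive_heart_disease,both,70,80,1.12,1.04,1.21
hypertensive_heart_disease,both,80,100,1.06,1.02,1.11
stroke,both,20,35,1.00,1.00,1.00
stroke,both,35,45,1.14,1.05,1.23
stroke,both,45,60,1.10,1.03,1.16
stroke,both,60,70,1.08,1.03,1.13
stroke,both,70,80,1.05,1.02,1.09
stroke,both,80,100,1.03,1.01,1.05
diabetes,both,20,35,1.00,1.00,1.00
diabetes,both,35,45,1.19,1.06,1.32
diabetes,both,45,70,1.14,1.05,1.23
diabetes,both,70,100,1.10,1.03,1.16
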