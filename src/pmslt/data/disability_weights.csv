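disease,sex,weight
colon_cancer,male,0.12
colon_cancer,female,0.11
breast_cancer,male,0.00
breast_cancer,female,0.12
endometrial_cancer,male,0.00
endometrial_cancer,female,0.03
kidney_cancer,male,0.06
kidney_cancer,female,0.06
ischemic_heart_disease,male,0.04
ischemic_heart_disease,female,0.06
stroke,male,0.31
stroke,female,0.31
hypertensive_heart_disease,male,0.09
hypertensive_heart_disease,female,0.07
diabetes,male,0.08
diabetes,female,0.08
osteoarthritis,male,0.05
osteoarthritis,female,0.06
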