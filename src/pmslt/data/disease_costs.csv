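disease,sex,age_lo,cost,basis
colon_cancer,male,0,17490,per_incident_case
colon_cancer,male,55,17657,per_incident_case
colon_cancer,male,65,18164,per_incident_case
colon_cancer,male,75,18037,per_incident_case
colon_cancer,male,85,19288,per_incident_case
kidney_cancer,male,0,16298,per_incident_case
kidney_cancer,male,55,16751,per_incident_case
kidney_cancer,male,65,14748,per_incident_case
kidney_cancer,male,75,14526,per_incident_case
kidney_cancer,male,85,7372,per_incident_case
ischemic_heart_disease,male,0,2962,per_prevalent_case_year
ischemic_heart_disease,male,55,1988,per_prevalent_case_year
ischemic_heart_disease,male,65,1664,per_prevalent_case_year
ischemic_heart_disease,male,75,1512,per_prevalent_case_year
ischemic_heart_disease,male,85,1394,per_prevalent_case_year
stroke,male,0,2228,per_prevalent_case_year
stroke,male,55,4942,per_prevalent_case_year
stroke,male,65,9529,per_prevalent_case_year
stroke,male,75,12856,per_prevalent_case_year
stroke,male,85,16301,per_prevalent_case_year
hypertensive_heart_disease,male,0,13103,per_prevalent_case_year
hypertensive_heart_disease,male,55,24408,per_prevalent_case_year
hypertensive_heart_disease,male,65,15048,per_prevalent_case_year
hypertensive_heart_disease,male,75,8167,per_prevalent_case_year
hypertensive_heart_disease,male,85,1723,per_prevalent_case_year
diabetes,male,0,504,per_prevalent_case_year
diabetes,male,55,660,per_prevalent_case_year
diabetes,male,65,763,per_prevalent_case_year
diabetes,male,75,639,per_prevalent_case_year
diabetes,male,85,594,per_prevalent_case_year
osteoarthritis,male,0,4431,per_prevalent_case_year
osteoarthritis,male,55,4431,per_prevalent_case_year
osteoarthritis,male,65,4431,per_prevalent_case_year
osteoarthritis,male,75,4431,per_prevalent_case_year
osteoarthritis,male,85,4431,per_prevalent_case_year
all_other,male,0,1555,per_person_year
all_other,male,55,2828,per_person_year
all_other,male,65,4731,per_person_year
all_other,male,75,7945,per_person_year
all_other,male,85,13061,per_person_year
colon_cancer,female,0,17136,per_incident_case
colon_cancer,female,55,16349,per_incident_case
colon_cancer,female,65,17238,per_incident_case
colon_cancer,female,75,17360,per_incident_case
colon_cancer,female,85,16545,per_incident_case
breast_cancer,female,0,12424,per_incident_case
breast_cancer,female,55,10493,per_incident_case
breast_cancer,female,65,11609,per_incident_case
breast_cancer,female,75,12706,per_incident_case
breast_cancer,female,85,12520,per_incident_case
endometrial_cancer,female,0,10665,per_incident_case
endometrial_cancer,female,55,9902,per_incident_case
endometrial_cancer,female,65,14419,per_incident_case
endometrial_cancer,female,75,10497,per_incident_case
endometrial_cancer,female,85,13402,per_incident_case
kidney_cancer,female,0,15505,per_incident_case
kidney_cancer,female,55,16363,per_incident_case
kidney_cancer,female,65,17133,per_incident_case
kidney_cancer,female,75,17198,per_incident_case
kidney_cancer,female,85,12192,per_incident_case
ischemic_heart_disease,female,0,1832,per_prevalent_case_year
ischemic_heart_disease,female,55,1520,per_prevalent_case_year
ischemic_heart_disease,female,65,1595,per_prevalent_case_year
ischemic_heart_disease,female,75,1564,per_prevalent_case_year
ischemic_heart_disease,female,85,1670,per_prevalent_case_year
stroke,female,0,1161,per_prevalent_case_year
stroke,female,55,2090,per_prevalent_case_year
stroke,female,65,5106,per_prevalent_case_year
stroke,female,75,13137,per_prevalent_case_year
stroke,female,85,19679,per_prevalent_case_year
hypertensive_heart_disease,female,0,22097,per_prevalent_case_year
hypertensive_heart_disease,female,55,32044,per_prevalent_case_year
hypertensive_heart_disease,female,65,20357,per_prevalent_case_year
hypertensive_heart_disease,female,75,9624,per_prevalent_case_year
hypertensive_heart_disease,female,85,1695,per_prevalent_case_year
diabetes,female,0,506,per_prevalent_case_year
diabetes,female,55,759,per_prevalent_case_year
diabetes,female,65,839,per_prevalent_case_year
diabetes,female,75,745,per_prevalent_case_year
diabetes,female,85,429,per_prevalent_case_year
osteoarthritis,female,0,4431,per_prevalent_case_year
osteoarthritis,female,55,4431,per_prevalent_case_year
osteoarthritis,female,65,4431,per_prevalent_case_year
osteoarthritis,female,75,4431,per_prevalent_case_year
osteoarthritis,female,85,4431,per_prevalent_case_year
all_other,female,0,2009,per_person_year
all_other,female,55,3225,per_person_year
all_other,female,65,4829,per_person_year
all_other,female,75,8197,per_person_year
all_other,female,85,15078,per_person_year
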