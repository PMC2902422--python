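# Reconstructed default map: 27 model causes -> 14 broad groups.
# The model's true cause list is not public; this list covers every cause
# named in the source study and is user-replaceable (same CSV dialect).
source_code,group
hiv_aids_related,hiv_aids
pulmonary_tuberculosis,pulmonary_tb
pneumonia_ari,pneumonia
malaria,malaria
meningitis,meningitis
acute_diarrhoeal_disease,diarrheal
persistent_diarrhoeal_disease,diarrheal
measles,measles
pertussis,other_acute_infectious
tetanus,other_acute_infectious
typhoid_fever,other_acute_infectious
rabies,other_acute_infectious
septicaemia,other_acute_infectious
maternity_related_death,maternity_related
preterm_birth_complications,preterm_perinatal
birth_asphyxia,preterm_perinatal
neonatal_pneumonia_sepsis,preterm_perinatal
congenital_abnormality,preterm_perinatal
malnutrition,malnutrition
cardiovascular_disease,noncommunicable_chronic
chronic_liver_disease,noncommunicable_chronic
kidney_disease,noncommunicable_chronic
neoplasm_cancer,noncommunicable_chronic
diabetes_mellitus,noncommunicable_chronic
chronic_respiratory_disease,noncommunicable_chronic
accident_injury,injuries
other_and_unspecified,other_unspecified
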