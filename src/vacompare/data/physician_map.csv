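# Reconstructed default map: 60-code abridged ICD-10 physician list -> 14 broad groups.
# The study's abridged code list is not public; this reconstruction keeps every
# cause named in the source study's text and is user-replaceable.
source_code,group
A01_typhoid_fever,other_acute_infectious
A06_amoebiasis,diarrheal
A09_diarrhoeal_disease,diarrheal
A15_pulmonary_tuberculosis,pulmonary_tb
A17_tuberculosis_other,other_acute_infectious
A33_tetanus,other_acute_infectious
A37_whooping_cough,other_acute_infectious
A39_meningococcal_infection,meningitis
A41_septicaemia,other_acute_infectious
A82_rabies,other_acute_infectious
A90_dengue_fever,other_acute_infectious
B05_measles,measles
B16_acute_hepatitis,other_acute_infectious
B24_hiv_aids,hiv_aids
B50_malaria,malaria
G00_bacterial_meningitis,meningitis
J18_pneumonia,pneumonia
J22_acute_lower_respiratory_infection,pneumonia
C15_oesophageal_cancer,noncommunicable_chronic
C50_breast_cancer,noncommunicable_chronic
C76_cancer_other_unspecified,noncommunicable_chronic
D64_anaemia,noncommunicable_chronic
E10_diabetes_mellitus,noncommunicable_chronic
G40_epilepsy,noncommunicable_chronic
I10_hypertensive_disease,noncommunicable_chronic
I21_acute_myocardial_infarction,noncommunicable_chronic
I50_heart_failure,noncommunicable_chronic
I64_stroke,noncommunicable_chronic
J44_chronic_obstructive_pulmonary_disease,noncommunicable_chronic
J45_asthma,noncommunicable_chronic
K35_acute_abdomen,noncommunicable_chronic
K70_liver_cirrhosis,noncommunicable_chronic
K92_gastrointestinal_haemorrhage,noncommunicable_chronic
N18_chronic_kidney_disease,noncommunicable_chronic
E40_kwashiorkor,malnutrition
E41_marasmus,malnutrition
E46_malnutrition_unspecified,malnutrition
O06_abortion_related,maternity_related
O15_eclampsia,maternity_related
O46_antepartum_haemorrhage,maternity_related
O72_postpartum_haemorrhage,maternity_related
O75_obstructed_labour,maternity_related
O85_puerperal_sepsis,maternity_related
P07_prematurity,preterm_perinatal
P15_birth_injury,preterm_perinatal
P21_birth_asphyxia,preterm_perinatal
P36_neonatal_sepsis,preterm_perinatal
P59_neonatal_jaundice,preterm_perinatal
Q89_congenital_malformation,preterm_perinatal
V89_road_traffic_accident,injuries
W19_fall,injuries
W65_drowning,injuries
X09_burns,injuries
X49_accidental_poisoning,injuries
X70_intentional_self_harm,injuries
X95_assault_firearm,injuries
Y09_assault_other,injuries
R95_sudden_infant_death,other_unspecified
R98_unattended_death,other_unspecified
R99_undetermined_cause,other_unspecified
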