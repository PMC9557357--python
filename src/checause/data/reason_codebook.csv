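code,group
heart_disease,NCD
diabetes,NCD
cancer,NCD
chronic_respiratory,NCD
stroke,NCD
depression_anxiety,NCD
malaria_fever,CD
tuberculosis,CD
diarrhoeal_disease,CD
acute_respiratory_infection,CD
childbirth_maternal,CD
child_illness_vaccination,CD
road_traffic_injury,INJURY
other_injury,INJURY
back_or_joint_pain,PAIN
planned_surgery,SURGERY
other_reason,OTHER
dont_know,UNIDENTIFIED
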