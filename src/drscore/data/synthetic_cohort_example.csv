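patient_id,age,bmi,dm_duration,microvascular,macrovascular,insulin_use,c_peptide_stim,hba1c,procedure,on_medication,remission
IISG-S42-001,54.65,21.0,6.61,0,1,0,4.37,8.97,IISG,1,0
IISG-S42-002,54.0,22.54,20.39,0,1,0,5.43,8.57,IISG,1,0
IISG-S42-003,44.88,23.28,11.13,0,0,0,4.12,8.09,IISG,1,1
IISG-S42-004,45.32,22.11,8.14,0,0,0,4.13,7.65,IISG,1,1
IISG-S42-005,36.69,30.03,6.76,0,0,0,4.62,8.54,IISG,1,1
IISG-S42-006,56.24,27.83,10.35,1,0,1,4.27,7.82,IISG,1,0
IISG-S42-007,35.59,30.44,6.69,1,0,1,2.06,8.12,IISG,1,0
IISG-S42-008,36.84,26.68,18.04,1,0,0,3.27,7.77,IISG,1,0
IISG-S42-009,40.0,28.12,13.82,1,1,0,4.16,8.74,IISG,1,0
IISG-S42-010,32.99,23.44,5.67,0,0,1,4.13,7.44,IISG,1,0
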