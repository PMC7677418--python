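feature,man,woman,boy,girl,elderly_man,elderly_woman,pregnant_woman,baby,large_man,large_woman,athletic_man,athletic_woman,male_executive,female_executive,male_doctor,female_doctor,homeless,criminal,dog,cat
Intervene,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
Male,1,0,1,0,1,0,0,0,1,0,1,0,1,0,1,0,0,0,0,0
Female,0,1,0,1,0,1,1,0,0,1,0,1,0,1,0,1,0,0,0,0
Young,0,0,1,1,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
Old,0,0,0,0,1,1,0,0,0,0,0,0,0,0,0,0,0,0,0,0
Infancy,0,0,0,0,0,0,0,1,0,0,0,0,0,0,0,0,0,0,0,0
Pregnancy,0,0,0,0,0,0,1,0,0,0,0,0,0,0,0,0,0,0,0,0
Large,0,0,0,0,0,0,0,0,1,1,0,0,0,0,0,0,0,0,0,0
Fit,0,0,0,0,0,0,0,0,0,0,1,1,0,0,0,0,0,0,0,0
Executive,0,0,0,0,0,0,0,0,0,0,0,0,1,1,0,0,0,0,0,0
Doctor,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1,1,0,0,0,0
Homeless,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1,0,0,0
Criminal,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1,0,0
Human,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,0,0
NonHuman,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1,1
Passenger,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
Legal,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
Illegal,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
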