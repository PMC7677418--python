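feature,mean,Intervene,Male,Female,Young,Old,Infancy,Pregnancy,Large,Fit,Executive,Doctor,Homeless,Criminal,Human,NonHuman,Passenger,Legal,Illegal
Intervene,-0.1,0.36,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0
Male,0.2,0.0,0.25,-0.05,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0
Female,0.5,0.0,-0.05,0.25,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0
Young,1.0,0.0,0.0,0.0,0.64,-0.144,0.192,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0
Old,-0.5,0.0,0.0,0.0,-0.144,0.36,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0
Infancy,1.2,0.0,0.0,0.0,0.192,0.0,0.64,0.256,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0
Pregnancy,1.0,0.0,0.0,0.0,0.0,0.0,0.256,0.64,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0
Large,-0.1,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.16,-0.032,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0
Fit,0.3,0.0,0.0,0.0,0.0,0.0,0.0,0.0,-0.032,0.16,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0
Executive,0.2,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.25,0.075,0.0,0.0,0.0,0.0,0.0,0.0,0.0
Doctor,0.6,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.075,0.36,0.0,0.0,0.0,0.0,0.0,0.0,0.0
Homeless,-0.3,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.36,0.135,0.0,0.0,0.0,0.0,0.0
Criminal,-1.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.135,0.81,0.0,0.0,0.0,0.0,0.0
Human,1.5,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,1.0,-0.245,0.0,0.0,0.0
NonHuman,-0.8,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,-0.245,0.49,0.0,0.0,0.0
Passenger,0.1,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.25,0.0,0.0
Legal,0.5,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.36,-0.168
Illegal,-0.7,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,-0.168,0.49
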