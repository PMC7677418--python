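feature,0.5,1,1.5,2,2.5
Intervene,0.77,1.5,-0.37,-0.69,2.61
Male,0.25,-1.66,-1.28,1.24,2.05
Female,-0.8,0.52,0.0,-0.8,1.59
Young,0.34,-0.76,-1.35,3.79,-4.59
Old,0.01,-0.1,1.99,-1.84,4.19
Infancy,-0.15,-0.87,-1.84,-1.05,1.1
Pregnancy,-0.09,-0.23,-2.31,3.45,-2.68
Large,0.51,-1.95,-2.86,3.52,-4.36
Fit,0.59,1.01,-0.86,1.57,0.88
Executive,0.76,1.05,-1.82,-1.31,4.55
Doctor,-0.53,-0.2,1.17,2.86,1.2
Homeless,0.88,-1.33,2.82,2.4,1.58
Criminal,-0.34,0.9,2.47,-2.14,4.11
Human,0.66,-0.88,-1.78,2.82,1.7
NonHuman,0.59,-0.42,-1.34,1.43,-3.88
Passenger,0.84,-1.95,0.05,1.07,1.26
Legal,-0.07,-1.55,-1.38,0.73,-1.67
Illegal,0.59,-1.31,1.17,-2.9,-1.9
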