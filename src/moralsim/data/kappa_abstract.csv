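feature,0.5,1,1.5,2,2.5
value1,-0.96,1.35,1.38,-2.52,3.79
value2,0.64,1.45,-1.89,-1.9,0.93
value3,-0.54,0.42,1.9,2.24,1.65
value4,-0.33,0.65,1.27,-2.79,-1.5
value5,0.08,0.89,-1.18,2.59,1.76
value6,-0.41,-0.32,-0.82,2.8,-2.95
value7,-0.06,-1.41,-1.7,1.01,2.65
value8,0.7,1.4,1.97,-1.6,-2.12
value9,-0.51,0.95,-0.65,-2.97,1.5
value10,0.15,1.15,-1.35,1.05,2.67
value11,0.87,-1.3,-0.8,-2.55,3.32
value12,0.8,-1.07,1.92,2.1,-3.85
value13,0.96,0.34,1.77,-0.92,-0.41
value14,-0.28,1.4,1.7,2.1,3.92
value15,0.49,-0.49,-1.96,1.91,3.95
value16,0.23,-1.34,-1.54,-1.13,-2.98
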