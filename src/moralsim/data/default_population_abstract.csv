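feature,mean,value1,value2,value3,value4,value5,value6,value7,value8,value9,value10,value11,value12,value13,value14,value15,value16
value1,0.552,0.6691,0.1078,-0.0024,-0.0225,-0.1114,0.0238,0.0411,-0.0947,0.0051,-0.0289,0.0936,0.1885,-0.0384,0.0138,0.0358,-0.0203
value2,0.288,0.1078,1.3806,0.1736,-0.0309,0.0579,-0.2279,0.0671,0.3553,0.0638,0.0738,-0.0346,0.1678,0.011,-0.098,0.0977,0.2226
value3,-2.082,-0.0024,0.1736,0.937,0.0666,-0.0706,-0.034,0.0409,0.223,-0.0514,-0.0668,-0.0176,-0.0658,0.1324,0.0956,-0.0986,-0.1174
value4,-0.507,-0.0225,-0.0309,0.0666,0.8427,0.0431,0.1625,0.0657,0.0091,0.1631,-0.0462,-0.0368,-0.1307,0.0867,-0.0436,0.1896,0.0322
value5,-0.151,-0.1114,0.0579,-0.0706,0.0431,0.2873,0.0223,-0.0331,0.0809,-0.0085,0.0557,-0.001,-0.0126,-0.0537,-0.0109,0.0905,-0.0084
value6,-0.157,0.0238,-0.2279,-0.034,0.1625,0.0223,0.5837,-0.056,-0.0735,-0.0979,-0.0115,-0.0223,0.0345,0.2272,-0.0187,-0.1209,-0.0526
value7,-0.855,0.0411,0.0671,0.0409,0.0657,-0.0331,-0.056,0.5069,0.087,-0.0481,-0.04,0.0179,-0.065,0.0778,0.1136,-0.0731,-0.0004
value8,0.396,-0.0947,0.3553,0.223,0.0091,0.0809,-0.0735,0.087,0.863,-0.0877,-0.0144,-0.0478,0.0885,0.1661,0.0424,-0.0953,-0.074
value9,0.022,0.0051,0.0638,-0.0514,0.1631,-0.0085,-0.0979,-0.0481,-0.0877,0.6675,-0.0124,-0.0745,0.0743,-0.0489,-0.0267,0.2364,0.1901
value10,0.003,-0.0289,0.0738,-0.0668,-0.0462,0.0557,-0.0115,-0.04,-0.0144,-0.0124,0.2704,-0.0082,-0.0591,-0.0044,0.0211,0.0531,0.1074
value11,-1.515,0.0936,-0.0346,-0.0176,-0.0368,-0.001,-0.0223,0.0179,-0.0478,-0.0745,-0.0082,0.2725,0.0232,0.007,0.0067,0.0257,-0.079
value12,-1.048,0.1885,0.1678,-0.0658,-0.1307,-0.0126,0.0345,-0.065,0.0885,0.0743,-0.0591,0.0232,1.1837,-0.0459,-0.1598,-0.0181,-0.1504
value13,1.364,-0.0384,0.011,0.1324,0.0867,-0.0537,0.2272,0.0778,0.1661,-0.0489,-0.0044,0.007,-0.0459,0.5929,-0.0093,-0.0847,-0.0006
value14,-0.498,0.0138,-0.098,0.0956,-0.0436,-0.0109,-0.0187,0.1136,0.0424,-0.0267,0.0211,0.0067,-0.1598,-0.0093,0.573,-0.1036,-0.0746
value15,-0.188,0.0358,0.0977,-0.0986,0.1896,0.0905,-0.1209,-0.0731,-0.0953,0.2364,0.0531,0.0257,-0.0181,-0.0847,-0.1036,1.4376,0.3925
value16,-0.541,-0.0203,0.2226,-0.1174,0.0322,-0.0084,-0.0526,-0.0004,-0.074,0.1901,0.1074,-0.079,-0.1504,-0.0006,-0.0746,0.3925,1.0568
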