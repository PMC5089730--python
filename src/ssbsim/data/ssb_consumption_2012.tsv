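sex	age_group	n_sample	population	volume_ml	volume_se	servings	servings_se
men	35-44	248	6537458	529.4	53.1	1.49	0.15
men	45-54	237	6953571	463.2	33.4	1.30	0.09
men	55-64	184	4053496	418.1	67.4	1.18	0.19
men	65-74	214	2857241	325.1	57.9	0.92	0.16
men	75-94	137	1869730	245.7	48.3	0.69	0.14
men	total	1020	22271496	438.4	24.5	1.24	0.07
women	35-44	400	8744682	385.1	26.8	1.08	0.08
women	45-54	277	6519086	336.2	33.4	0.95	0.09
women	55-64	225	4593913	203.1	32.9	0.57	0.09
women	65-74	239	2671939	219.2	24.6	0.62	0.07
women	75-94	177	2006184	186.0	22.8	0.52	0.06
women	total	1318	24535804	303.7	15.0	0.86	0.04
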