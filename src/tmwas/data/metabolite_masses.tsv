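metabolite_id	name	formula	mass
M001	D-glucose	C6H12O6	180.06339
M002	pyruvate	C3H4O3	88.01604
M003	L-lactate	C3H6O3	90.03169
M004	glycerol-3-phosphate	C3H9O6P	172.01367
M005	fructose-6-phosphate	C6H13O9P	260.02972
M006	citrate	C6H8O7	192.02700
M007	succinate	C4H6O4	118.02661
M008	fumarate	C4H4O4	116.01096
M009	malate	C4H6O5	134.02152
M010	2-oxoglutarate	C5H6O5	146.02152
M011	L-glutamate	C5H9NO4	147.05316
M012	L-glutamine	C5H10N2O3	146.06914
M013	L-alanine	C3H7NO2	89.04768
M014	glycine	C2H5NO2	75.03203
M015	L-serine	C3H7NO3	105.04259
M016	L-aspartate	C4H7NO4	133.03751
M017	L-methionine	C5H11NO2S	149.05105
M018	L-cysteine	C3H7NO2S	121.01975
M019	L-tryptophan	C11H12N2O2	204.08988
M020	L-histidine	C6H9N3O2	155.06948
M021	hypoxanthine	C5H4N4O	136.03851
M022	inosine	C10H12N4O5	268.08077
M023	uric-acid	C5H4N4O3	168.02834
M024	adenine	C5H5N5	135.05450
M025	uracil	C4H4N2O2	112.02728
M026	nicotinamide	C6H6N2O	122.04801
M027	nicotinate	C6H5NO2	123.03203
M028	glutathione	C10H17N3O6S	307.08381
M029	glutathione-disulfide	C20H32N6O12S2	612.15196
M030	linolenate	C18H30O2	278.22458
M031	stearate	C18H36O2	284.27153
M032	carnitine	C7H15NO3	161.10519
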