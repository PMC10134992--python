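P01	glycolysis	M001	M002	M003	M004	M005
P02	tca_cycle	M006	M007	M008	M009	M010
P03	amino_acid_metabolism	M011	M012	M013	M014	M015	M016	M020
P04	sulfur_amino_acid_glutathione	M017	M018	M028	M029
P05	purine_pyrimidine	M021	M022	M023	M024	M025
P06	nicotinate_nicotinamide	M026	M027
P07	fatty_acid_metabolism	M030	M031	M032
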