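haplotype	all_dogs	afghan_hound	basenji	siberian_husky	chihuahua	greyhound	boxer	labrador_retriever	pembroke_welsh_corgi	beagle	doberman_pinscher	golden_retriever	german_shepherd	standard_poodle
*1A(17)	0.257	0.200	0.000	1.000	0.300	0.071	0.932	0.125	0.100	0.115	0.000	0.300	0.545	0.045
*1A(18)	0.004	0.000	0.200	0.000	0.000	0.000	0.000	0.000	0.000	0.000	0.000	0.000	0.000	0.000
*1B(17)	0.086	0.000	0.000	0.000	0.000	0.286	0.023	0.125	0.000	0.231	0.000	0.000	0.091	0.045
*2A(16)	0.077	0.000	0.000	0.000	0.200	0.071	0.000	0.063	0.100	0.038	0.333	0.200	0.000	0.318
*2B(17)	0.013	0.000	0.000	0.000	0.100	0.000	0.000	0.000	0.000	0.000	0.000	0.000	0.045	0.000
*3A(11)	0.081	0.600	0.500	0.000	0.000	0.571	0.023	0.125	0.100	0.000	0.000	0.000	0.000	0.000
*5A(17)	0.011	0.000	0.000	0.000	0.100	0.000	0.000	0.000	0.000	0.077	0.000	0.000	0.000	0.000
*6A(16)	0.218	0.100	0.100	0.000	0.100	0.000	0.000	0.438	0.300	0.269	0.417	0.050	0.182	0.227
*6A(17)	0.027	0.000	0.000	0.000	0.000	0.000	0.000	0.000	0.000	0.000	0.000	0.000	0.136	0.000
*7A(16)	0.005	0.000	0.000	0.000	0.000	0.000	0.000	0.000	0.200	0.000	0.000	0.000	0.000	0.000
*8A(19)	0.013	0.000	0.000	0.000	0.000	0.000	0.000	0.000	0.000	0.000	0.000	0.000	0.000	0.318
*9A(16)	0.072	0.100	0.000	0.000	0.100	0.000	0.000	0.063	0.200	0.154	0.083	0.300	0.000	0.000
*10A(16)	0.040	0.000	0.000	0.000	0.000	0.000	0.000	0.063	0.000	0.077	0.167	0.000	0.000	0.000
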