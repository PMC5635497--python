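haplotype	freq_dog	freq_wolf	freq_coyote
*1A(17)	0.257	0.179	0.071
*1C(10)	0.007	0.000	0.286
*1H(17)	0.000	0.286	0.000
*1H(13)	0.000	0.143	0.000
*2A(16)	0.077	0.000	0.000
*3A(11)	0.081	0.071	0.000
*6A(16)	0.218	0.036	0.000
*10A(16)	0.040	0.000	0.000
*11A(16)	0.090	0.071	0.143
*17A(20)	0.000	0.036	0.071
*19A(20)	0.000	0.000	0.071
*20A(17)	0.000	0.000	0.071
*21A(12)	0.000	0.000	0.214
*22A(12)	0.000	0.000	0.071
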