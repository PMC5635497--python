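name	shorthand	freq_dog	freq_wolf	freq_coyote	varscore	dg
10	GCT(GCC)_7ACCGCC	0.007	0.000	0.286	0.58	-5.6
11	GCT(GCC)_8ACCGCC	0.099	0.000	0.000	0.75	-8.5
12*1	GCT(GCC)_9ACCGCC	0.000	0.040	0.000	0.88	-9.5
12*2	GCT(GCC)_3GCTGCCACTGCTACCGCCACCGCC	0.000	0.000	0.286	0.72	-4.8
13	GCT(GCC)_10ACCGCC	0.000	0.180	0.000	0.97	-11.5
14	GCT(GCC)_13	0.013	0.000	0.000	1.09	-14.5
15	GCT(GCC)_14	0.005	0.000	0.000	1.12	-17.5
16*1	GCT(GCC)_15	0.302	0.140	0.000	1.13	-17.5
16*2	GCT(GCC)_3GCTGCCACTGCTACC(GCC)_3ACCGCCACCGCC	0.124	0.000	0.143	0.58	-7.3
17	GCT(GCC)_5GCT(GCC)_8ACCGCC	0.424	0.214	0.143	1.10	-14.4
18	GCT(GCC)_5GCT(GCC)_9ACCGCC	0.009	0.285	0.000	1.10	-18.0
19	GCT(GCC)_5GCT(GCC)_6ACCGCCACCGCCACCGCC	0.013	0.000	0.000	1.07	-14.4
20	GCT(GCC)_3GCTGCCACTGCTACC(GCC)_3ACC(GCC)_3ACCGCCACCGCC	0.000	0.140	0.143	.	-11.4
22*1	GCT(GCC)_3GCTGCAACTGCTACC(GCC)_3ACTGCTACC(GCC)_3ACCGCCACCGCC	0.002	0.000	0.000	0.64	-11.0
22*2	GCT(GCC)_3GCTGCAACTGCTACC(GCC)_2ACTGCTACC(GCC)_4ACCGCCACCGCC	0.002	0.000	0.000	.	-13.3
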