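id	chr_position	c_label	vtype	ref	alt	freq_dog	freq_wolf	freq_coyote
ss2019497428	49908119	c.-21 A > G	substitution	A	G	0.356	0.143	0.000
ss2019497429	49908125	c.-27 G > A	substitution	G	A	0.257	0.257	0.429
ss3021042895	49908135	c.-37 C > T	substitution	C	T	0.002	0.000	0.286
ss3021042898	49908141	c.-43 C > T	substitution	C	T	0.138	0.036	0.429
rs22633673	49908144	c.-46 T > C	substitution	T	C	0.496	0.857	0.643
ss2019497431	49908166	c.-68 C > T	substitution	C	T	0.131	0.036	0.214
.	49908180	c.-82 C > T	substitution	C	T	0.000	0.143	0.143
ss2019497432	49908225	c.-127 G > C	substitution	G	C	0.009	0.000	0.000
.	49908277	c.-179 G > C	substitution	G	C	0.000	0.143	0.071
ss2019497433	49908283	c.-185 delT	single_base_deletion	T	-	0.079	0.000	0.000
rs22646524	49908326	c.-228 C > A	substitution	C	A	0.464	0.107	0.143
ss2019497435-6	49908403	c.-305 (GCCCTC)_2	tandem_repeat_length	4	2	0.000	0.143	0.214
ss2019497435-6	49908403	c.-305 (GCCCTC)_3	tandem_repeat_length	4	3	0.049	0.036	0.000
ss2019497435-6	49908403	c.-305 (GCCCTC)_5	tandem_repeat_length	4	5	0.002	0.000	0.000
rs22646522	49908448	c.-350 C > A	substitution	C	A	0.379	0.107	0.286
ss2019497438	49908506	c.-408 C > G	substitution	C	G	0.013	0.000	0.286
ss2019497439	49908620	c.-522 G > A	substitution	G	A	0.005	0.000	0.000
.	49908637	c.-539 C > T	substitution	C	T	0.000	0.036	0.286
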