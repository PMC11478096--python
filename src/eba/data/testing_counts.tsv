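class	total	exp_within	pred_within	exp_below	pred_below	exp_above	pred_above
Mu	1706	981	979	355	349	370	335
Sigma	694	592	592	66	66	36	36
Alpha	1520	734	734	495	471	291	289
Pi	609	323	323	158	158	128	124
Theta	1428	560	560	545	540	323	323
Delta-Epsilon	822	715	715	68	68	39	39
Omega	1349	556	556	617	597	176	176
Zeta	728	268	268	122	122	338	338
DHAR	10	0	0	7	7	3	3
Tau	1342	851	851	222	219	269	268
Phi	1711	1066	1066	177	177	468	468
HSP26	433	363	363	48	48	22	22
LanC	450	177	177	109	109	164	164
Kappa	1148	230	230	554	554	364	364
MAPEG	1111	687	687	143	143	281	281
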