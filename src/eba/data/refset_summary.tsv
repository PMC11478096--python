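class	bacteria	amoebozoa	fungi	viridiplantae	platyhelminthes	nematoda	arthropoda	mollusca	actinopterygii	amphibia	aves	mammalia	total	min_len	max_len
Mu	0	0	0	0	11	0	3	0	0	0	1	28	43	211	225
Sigma	0	0	0	0	0	9	7	1	0	0	1	3	21	199	249
Alpha	0	1	0	0	0	0	0	0	0	0	2	18	21	222	229
Pi	0	0	0	0	0	5	0	0	0	2	0	12	19	207	210
Theta	0	0	0	0	0	0	0	0	0	0	0	12	12	240	244
Delta-Epsilon	0	0	0	0	0	0	32	0	0	0	0	0	32	208	271
Omega	0	0	0	0	0	3	2	0	0	0	0	7	12	240	256
Zeta	3	0	1	3	0	1	0	0	0	0	0	3	11	212	221
Rho	0	0	0	0	0	0	0	1	1	0	0	0	2	223	225
DHAR	0	0	0	3	0	0	0	0	0	0	0	0	3	213	213
Tau	0	0	0	34	0	0	0	0	0	0	0	0	34	217	231
Phi	0	0	0	25	0	0	0	0	0	0	0	0	25	212	221
Lambda	0	0	0	3	0	0	0	0	0	0	0	0	3	235	237
Beta	4	0	0	0	0	0	0	0	0	0	0	0	4	201	203
HSP26	3	0	0	0	0	0	0	0	0	0	0	0	3	202	212
Omega-like	0	0	4	0	0	0	0	0	0	0	0	0	4	313	370
FosA	2	0	0	0	0	0	0	0	0	0	0	0	2	135	141
LanC	0	0	0	0	0	0	0	0	1	0	0	4	5	399	405
Kappa	0	0	0	0	0	2	0	0	0	0	0	3	5	225	226
MAPEG	0	1	0	0	0	0	0	0	0	0	0	22	23	146	155
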