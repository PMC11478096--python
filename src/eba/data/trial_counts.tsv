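row	bacteria	amoebozoa	fungi	viridiplantae	platyhelminthes	nematoda	arthropoda	mollusca	actinopterygii	amphibia	aves	mammalia	others	total
Mu	5	0	33	4	6	12	74	7	5	0	0	7	96	249
Sigma	30	0	87	14	0	480	133	82	11	3	73	130	376	1419
Alpha	21	0	13	7	0	11	1	1	2	0	1	6	49	112
Pi	0	0	37	2	0	6	4	0	0	1	0	4	33	87
Theta	13	0	0	10	0	0	1	3	2	0	0	30	5	64
Delta-Epsilon	1949	9	498	8	0	0	1642	1	5	0	0	4	74	4190
Omega	87	0	112	5	1	0	1	0	0	0	0	0	10	216
Zeta	1397	0	22	7	0	0	0	0	0	0	1	0	21	1448
Rho	524	0	22	0	0	0	0	5	197	0	0	0	9	757
DHAR	1	0	0	0	0	0	0	0	0	0	0	0	0	1
Tau	1555	0	30	2401	0	1	0	0	1	0	0	0	41	4029
Phi	3694	5	772	60	0	0	0	1	1	0	0	1	57	4591
Lambda	0	0	3	63	0	0	0	0	0	0	0	0	0	66
Beta	1569	0	4	0	0	0	1	0	0	0	0	0	15	1589
HSP26	2539	0	9	1	0	0	0	0	0	0	0	0	27	2576
Omega-like	2746	1	298	39	0	0	2	0	4	0	2	21	200	3313
FosA	306	0	0	0	0	0	0	0	0	0	0	0	2	308
LanC	0	0	0	0	0	0	0	0	0	0	0	0	1	1
Kappa	0	0	8	0	0	0	0	0	1	0	0	0	0	9
MAPEG	39	1	230	108	3	0	347	24	141	11	48	44	159	1155
Within RLR	16475	16	2178	2729	10	510	2206	124	370	15	125	247	1175	26180
Below RLR	11288	6	626	1493	66	237	443	52	426	39	159	509	677	16021
Above RLR	12917	22	3743	2260	18	119	388	45	342	15	56	148	1007	21080
Total	41075	44	6582	6851	99	883	3063	222	1157	69	345	928	2889	64207
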