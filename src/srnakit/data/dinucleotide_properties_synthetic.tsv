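oligo	Twist	Tilt	Roll	Shift	Slide	Rise
AA	0.0561	0.7885	-0.9417	0.8977	1.4654	0.5421
AC	-0.0496	-0.0623	0.5271	-1.2352	-0.8348	0.8272
AG	0.4821	0.2662	0.3085	0.2813	-1.6515	1.3929
AT	0.7438	-0.4776	-0.2795	-1.7725	-2.5224	-0.5983
CA	0.3476	0.8032	-0.7846	-0.2617	-1.1223	-0.7524
CC	-0.7788	0.5415	-1.1870	-0.8329	2.7448	-0.6541
CG	-1.3640	0.8998	0.0364	-1.4514	1.2218	0.1153
CT	0.1108	-0.0484	0.7174	0.5499	1.1304	-0.0276
GA	-0.8498	1.8396	0.5262	1.1875	-0.2279	0.7394
GC	-0.5537	-0.5229	0.6405	-1.0916	-2.2610	-0.9860
GG	-0.1541	-0.6693	0.8720	0.3422	0.1228	0.2718
GT	0.6171	-0.4326	-0.1699	-1.0927	1.6425	-0.1044
TA	-0.6887	-0.0728	0.6102	0.5668	0.0472	-1.1134
TC	0.9452	0.1990	0.3607	-1.5019	-2.3808	-0.2871
TG	1.4534	-1.4505	0.8833	-0.7748	0.3291	0.6243
TT	-0.7408	0.2373	-0.9014	-0.3497	-0.9674	0.8555
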