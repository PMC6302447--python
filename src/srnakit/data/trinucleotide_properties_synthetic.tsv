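oligo	Prop01	Prop02	Prop03	Prop04	Prop05	Prop06	Prop07	Prop08	Prop09	Prop10	Prop11	Prop12
AAA	-0.2467	1.6500	1.8646	-0.3005	1.4097	2.0089	-0.0788	0.2611	-0.0473	-1.6165	1.6397	0.5522
AAC	-1.1191	-0.8751	1.7724	0.0186	-0.1648	0.3092	-0.0955	-0.8352	0.2448	0.7952	0.1346	-0.3881
AAG	-0.4337	-0.0153	-0.0780	0.0700	0.9498	0.4638	-0.4230	0.4593	-0.4988	-0.9242	-0.0071	1.2758
AAT	-1.5288	-0.6228	-0.3248	-0.7872	-0.1690	0.2762	-0.4508	-1.4616	-1.0904	1.2715	0.7545	-0.5547
ACA	1.4490	0.3400	1.3019	-0.0407	0.5014	0.2084	0.3387	-0.4579	1.3966	-0.2101	-1.0946	0.3442
ACC	0.7582	-1.1878	1.8821	2.5896	-2.8820	-0.0693	0.4353	-0.9502	0.8578	-1.2916	0.1517	1.3357
ACG	1.4214	0.0245	0.4074	0.4978	-0.9359	1.2489	-0.7988	1.7131	-0.0238	0.8265	-1.0153	0.6074
ACT	-0.5419	-1.2119	-0.3835	0.8642	-0.3543	-1.3102	0.3231	-0.2771	1.7450	-1.8276	0.5916	1.2810
AGA	1.6303	0.3734	0.8216	-1.0830	0.9075	1.3800	1.7139	0.3765	-1.2203	0.0163	-0.2836	0.6598
AGC	0.5770	-0.6728	0.4467	1.7401	0.5721	-0.3358	0.0861	0.3356	0.7465	0.5787	-0.7042	1.6298
AGG	-0.6533	-0.9891	0.1826	0.3751	-0.3617	1.2414	-0.6009	-0.2871	0.5020	-0.8830	0.9785	0.7798
AGT	-1.8941	2.9134	0.9339	-2.1869	-1.8873	-0.6340	1.0264	-1.9156	1.1864	1.3098	-0.6877	1.1662
ATA	-1.4859	-0.1908	-1.7988	-0.4462	-1.3039	0.6135	-0.3597	-0.2576	0.3252	-0.1915	0.2573	-0.3918
ATC	-1.6631	-0.8404	-0.8717	-1.8187	-0.2248	-1.3326	-0.5098	-0.6119	-0.4731	-0.2730	-0.9772	0.5442
ATG	-0.3347	-0.5982	0.3048	1.7609	-0.2205	-0.7120	-0.6815	-0.6465	1.8214	-0.9538	-0.4356	-0.1652
ATT	-0.2951	-0.0379	-0.5381	1.7453	0.8082	0.0369	-0.4391	-1.7170	1.3585	-1.1326	0.6723	0.4147
CAA	0.3195	-0.3202	0.8756	1.2913	-0.7455	0.2811	1.4468	-1.0949	0.8473	0.1527	0.2207	1.2431
CAC	1.4506	-1.2532	-0.7587	-2.1304	-0.0475	-0.1515	0.0462	-2.0381	1.1003	-2.1666	0.0104	1.1543
CAG	0.3193	-0.6162	-0.2448	-0.1655	0.1526	-0.9946	0.4421	0.0478	-0.4116	0.8294	-0.1476	-0.1493
CAT	0.7975	-1.0741	0.5803	0.1345	-1.0324	-1.3554	-0.2540	1.2495	0.7658	0.1104	-0.0884	-0.0509
CCA	-0.1108	0.4241	-0.6151	1.9554	0.5448	0.3996	-0.2248	0.5754	0.9033	1.1992	0.7592	0.1610
CCC	1.8067	-2.5397	2.2526	0.4497	-2.8103	0.0703	0.9516	0.2877	-0.4868	0.9997	-0.8873	0.5846
CCG	0.6362	-1.1267	-1.8888	0.6969	0.8561	-1.3010	-2.9070	1.6458	-0.1840	1.6833	1.0183	-0.5127
CCT	0.0273	-0.7771	1.1552	-0.8238	-1.0207	-0.1650	-0.9304	-1.3076	1.6931	-1.6521	-0.5511	0.2900
CGA	-1.6293	-1.5195	0.0791	0.8652	0.0737	0.6224	-0.1553	0.2611	1.1858	-0.8007	-1.4202	-0.3716
CGC	-0.5511	-1.3256	2.1415	1.5552	-0.6021	0.1467	2.8109	1.3368	0.4228	-1.6684	-0.5279	-0.3524
CGG	-0.9261	-2.4672	0.0310	-0.6150	0.5911	-0.2146	0.0020	0.3400	-0.5366	0.0792	-0.9266	0.2458
CGT	-1.5221	0.8008	1.2352	-0.7365	-1.4185	-1.0709	-1.3863	0.0137	-0.1942	-0.5544	0.6124	0.0336
CTA	-1.2753	0.7605	2.4226	0.2840	-0.2455	0.3942	-0.9087	-1.5721	0.1500	-0.3132	-0.0991	-0.1595
CTC	-0.3274	-0.1217	-1.2523	-0.3184	-1.5288	0.5551	0.0254	-0.0065	0.5970	1.8030	1.3756	-2.6101
CTG	-0.8484	-0.2289	0.8562	1.0956	0.2459	0.8308	-0.6158	1.8290	0.8285	-0.4807	-0.0779	-0.3296
CTT	-0.6315	-0.1572	-1.0484	-0.3640	-2.1184	0.3261	-0.5909	0.2578	0.6495	1.1427	0.3914	-0.9168
GAA	0.1959	0.3489	-0.7350	-0.0019	-0.8469	-0.4273	-0.2853	-1.6436	0.0829	1.1170	-0.2818	0.5059
GAC	0.2360	-2.4298	-0.2491	0.3652	0.3540	-0.3428	0.0549	-0.7953	-0.6672	-1.7319	-0.2161	1.2045
GAG	0.6017	-0.4280	0.4936	-1.5290	-0.6616	-0.9641	0.2451	-0.5194	0.8407	0.3700	1.5032	-0.7461
GAT	1.0951	-0.4908	-1.4511	0.6779	0.2192	-1.3880	0.6601	0.2500	-0.3433	-1.3352	-1.4297	0.9980
GCA	-0.4834	1.1817	1.1713	2.0640	0.3291	1.3132	-0.2358	1.1574	1.0175	0.2564	0.9692	-0.0035
GCC	-0.3076	-0.5955	0.2666	-0.2767	-0.7130	1.0893	0.5199	0.0575	0.3560	-0.0233	-0.0268	1.1147
GCG	-0.2960	-0.1331	0.5475	0.8100	0.0793	0.1233	1.5469	-0.7917	-0.6811	-1.1539	-0.6219	0.9180
GCT	-0.2755	1.3220	-0.2164	0.5356	0.8097	2.3439	0.3407	-1.1075	1.1226	0.6270	-1.2250	0.8599
GGA	1.4294	-0.1697	-1.3216	1.2791	0.0301	-0.1543	-1.0585	0.4197	-0.0353	-0.2968	0.2814	-0.5516
GGC	1.1984	0.0956	1.9481	0.3602	-0.1330	2.5242	-0.0684	-0.7298	0.6607	1.0111	-0.8401	-0.3300
GGG	-2.0392	0.4592	-0.5109	0.7585	0.2068	0.2603	0.9078	0.0961	0.4693	-1.3347	-0.1675	-1.2850
GGT	-0.5783	0.6327	-0.7357	0.5147	-0.0562	0.3738	1.2591	1.2255	2.2272	-1.0888	1.5249	1.4412
GTA	-0.3053	0.0115	1.0467	0.9929	0.4110	1.8301	0.7157	0.1284	-0.2202	1.8600	0.4784	0.0469
GTC	0.8255	-0.5652	-0.9735	0.3323	0.4485	-0.7018	0.0312	0.5827	0.6749	-0.5577	0.6318	0.5471
GTG	0.3927	-1.9945	0.6539	-0.3087	0.3696	-0.7998	-0.6988	0.8849	1.4217	1.8005	-0.8352	-1.0393
GTT	-1.5286	0.2224	0.8328	0.7647	-1.2764	1.2822	-0.2498	-0.9281	-0.2195	-0.7850	-0.1413	0.7992
TAA	-0.4147	1.8611	1.7024	0.9478	0.3566	-0.4702	0.9240	0.2979	0.5900	0.8381	0.4277	0.1653
TAC	-0.1565	-0.6553	0.3078	0.1263	-1.8884	1.7431	-0.4821	0.4419	-0.7911	0.1391	0.9475	-0.3167
TAG	0.0040	0.7434	-0.2440	-0.0832	-0.0153	-0.2198	-1.3815	-1.4291	-1.4245	-0.0672	-1.3478	0.2731
TAT	-0.0507	-0.2878	2.5402	-0.2854	0.8675	-0.1053	-1.2133	-0.7294	-1.1159	-0.8562	-1.0046	-1.1593
TCA	0.9099	-0.3584	-0.9579	-1.2767	-0.9351	0.8331	-0.7307	0.7834	-0.5596	-0.6974	1.4388	-1.9490
TCC	-1.6343	1.0511	-0.0563	-0.1325	0.7013	2.2480	0.2115	-0.6654	-0.2130	0.5243	1.1623	0.5443
TCG	0.9593	0.7685	0.0781	-0.5380	0.2340	-0.8557	-0.6638	-0.3906	-0.0233	1.0135	-0.6460	-1.4399
TCT	0.8671	0.8044	-0.2787	-0.2740	-0.7871	-0.2782	0.0979	-0.8410	1.7862	1.0296	-2.1556	1.2922
TGA	1.4911	0.7410	-2.6076	-0.5339	-0.0248	0.5850	0.4054	1.7447	0.3604	-0.6510	-0.8335	-0.6177
TGC	-0.3914	0.1440	-2.4526	0.0454	-0.3565	-1.9316	0.2090	0.3453	0.5138	0.3431	-0.3422	-1.0634
TGG	0.8929	0.8470	-0.0580	-0.0385	0.5310	-1.1546	-0.0084	-0.5733	1.1665	1.0907	0.3409	-0.5710
TGT	-0.3611	0.3430	1.8734	-0.0147	1.0846	1.8141	-0.0365	1.9678	-1.5274	-0.3468	0.1447	0.4665
TTA	-0.5752	-0.2105	0.1859	0.1995	0.7912	0.9616	0.2994	0.4737	0.7327	-0.4823	-0.2757	0.0107
TTC	-1.7800	-0.7837	-0.0921	0.4714	0.1157	0.9261	-1.6070	-1.4496	-0.5089	1.4909	1.2166	0.5220
TTG	2.2049	1.1175	1.2484	-0.4733	-0.2721	0.1822	-0.5420	0.9645	0.4896	-0.4805	1.4398	0.5953
TTT	0.0690	-0.0762	1.5722	1.1785	0.2710	-0.3164	2.4376	-0.2532	-0.6153	-0.5980	1.1125	0.5075
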