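variant_id	chrom	pos	effect_allele	other_allele	freq	beta	se	pval	n
rs1	1	5000	A	C	0.37375	0.041667821	0.0065363535	1.8322479e-10	50000
rs2	1	10000	G	A	0.37	0.27847113	0.0065498124	2.2250739e-308	50000
rs3	1	15000	C	A	0.38	0.49395714	0.0065149691	2.2250739e-308	50000
rs4	1	20000	A	C	0.39625	0.19286992	0.0064652718	1.51751e-195	50000
rs5	1	25000	T	G	0.425	-0.0043777427	0.0063969302	0.49375384	50000
rs6	1	30000	C	A	0.415	-0.036057844	0.006417975	1.9289155e-08	50000
rs7	1	35000	T	C	0.39625	0.047747379	0.0064652718	1.5221488e-13	50000
rs8	1	40000	C	A	0.4075	-0.3073086	0.0064356441	2.2250739e-308	50000
rs9	1	45000	C	A	0.40625	-1.5486016	0.0064387491	2.2250739e-308	50000
rs10	1	50000	G	T	0.3825	-0.60347278	0.0065067751	2.2250739e-308	50000
rs11	1	55000	T	A	0.0975	-0.98767717	0.010660414	2.2250739e-308	50000
rs12	1	60000	T	G	0.09375	-1.1929694	0.010849016	2.2250739e-308	50000
rs13	1	65000	T	A	0.10375	-0.97564502	0.010370301	2.2250739e-308	50000
rs14	1	70000	G	A	0.0975	-0.70548693	0.010660414	2.2250739e-308	50000
rs15	1	75000	G	T	0.09	-0.61626379	0.011049892	2.2250739e-308	50000
rs16	1	80000	A	C	0.09625	-0.21388749	0.010721992	1.5449999e-88	50000
rs17	1	85000	G	T	0.08625	0.32967837	0.011264366	2.699574e-188	50000
rs18	1	90000	G	T	0.10875	0.40244573	0.010157471	2.2250739e-308	50000
rs19	1	95000	G	A	0.11375	0.24649646	0.0099596981	3.1474312e-135	50000
rs20	1	100000	C	A	0.105	-0.26153152	0.010315584	8.3168841e-142	50000
rs21	1	105000	T	C	0.125	0.52176049	0.0095618289	2.2250739e-308	50000
rs22	1	110000	C	A	0.13625	0.94616707	0.0092180214	2.2250739e-308	50000
rs23	1	115000	G	T	0.12	0.45274561	0.0097312368	2.2250739e-308	50000
rs24	1	120000	G	T	0.13375	0.054497307	0.0092903373	4.4637915e-09	50000
rs25	1	125000	G	A	0.13375	-0.23949156	0.0092903373	1.5424798e-146	50000
rs26	1	130000	T	A	0.1275	-1.0662587	0.0094811756	2.2250739e-308	50000
rs27	1	135000	A	C	0.13375	-0.28752386	0.0092903373	2.6450819e-210	50000
rs28	1	140000	C	A	0.125	0.0090441835	0.0095618289	0.34421829	50000
rs29	1	145000	T	C	0.12125	0.18977635	0.0096878288	1.9135101e-85	50000
rs30	1	150000	T	G	0.1325	0.51957996	0.0093273295	2.2250739e-308	50000
rs31	1	155000	T	C	0.1225	-0.65497819	0.0096451368	2.2250739e-308	50000
rs32	1	160000	G	A	0.1325	-0.68011527	0.0093273295	2.2250739e-308	50000
rs33	1	165000	C	A	0.1025	-0.27145118	0.010426075	1.9484926e-149	50000
rs34	1	170000	G	T	0.12125	-0.5750365	0.0096878288	2.2250739e-308	50000
rs35	1	175000	G	A	0.13	-0.70691645	0.009403049	2.2250739e-308	50000
rs36	1	180000	G	A	0.11625	-0.65193036	0.0098659476	2.2250739e-308	50000
rs37	1	185000	T	G	0.12875	-0.81594313	0.0094418041	2.2250739e-308	50000
rs38	1	190000	T	A	0.12875	-1.4535255	0.0094418041	2.2250739e-308	50000
rs39	1	195000	A	C	0.1225	-1.8540245	0.0096451368	2.2250739e-308	50000
rs40	1	200000	C	A	0.1175	-1.3289195	0.0098202764	2.2250739e-308	50000
rs41	1	205000	T	C	0.25375	-1.2813248	0.007266994	2.2250739e-308	50000
rs42	1	210000	G	A	0.24875	-1.3017617	0.0073152001	2.2250739e-308	50000
rs43	1	215000	T	G	0.24875	0.29540423	0.0073152001	2.2250739e-308	50000
rs44	1	220000	T	C	0.235	0.29404871	0.0074582228	2.2250739e-308	50000
rs45	1	225000	G	A	0.23625	-0.14808107	0.0074445505	4.8497259e-88	50000
rs46	1	230000	G	A	0.22875	0.22891179	0.0075287324	4.7045199e-203	50000
rs47	1	235000	A	C	0.2475	0.076697183	0.007327556	1.2252372e-25	50000
rs48	1	240000	T	G	0.2675	0.15224123	0.0071438823	9.0307735e-101	50000
rs49	1	245000	C	A	0.2375	0.11283578	0.0074310172	4.4842405e-52	50000
rs50	1	250000	G	C	0.225	0.40010786	0.0075728245	2.2250739e-308	50000
rs51	1	255000	C	A	0.25625	0.16455346	0.0072436019	3.037635e-114	50000
rs52	1	260000	T	C	0.22875	0.13470661	0.0075287324	1.353151e-71	50000
rs53	1	265000	G	C	0.25375	0.13938078	0.007266994	5.4404716e-82	50000
rs54	1	270000	A	C	0.25875	0.28741467	0.0072206695	2.2250739e-308	50000
rs55	1	275000	G	T	0.27375	-0.0040115511	0.0070921819	0.5716453	50000
rs56	1	280000	G	T	0.25875	-0.12112851	0.0072206695	3.7031738e-63	50000
rs57	1	285000	G	T	0.23	-0.13035771	0.0075143379	2.0471679e-67	50000
rs58	1	290000	T	G	0.25125	0.017256926	0.0072908564	0.017936465	50000
rs59	1	295000	A	C	0.275	-0.078222592	0.0070821423	2.3164733e-28	50000
rs60	1	300000	T	G	0.2875	-0.11874197	0.0069869662	8.976216e-65	50000
rs61	1	305000	A	C	0.505	0.059935986	0.0063248716	2.6361675e-21	50000
rs62	1	310000	T	G	0.515	0.080171054	0.0063274033	8.621716e-37	50000
rs63	1	315000	G	A	0.51875	-0.35816043	0.006329007	2.2250739e-308	50000
rs64	1	320000	T	G	0.49375	-0.91421031	0.0063250495	2.2250739e-308	50000
rs65	1	325000	A	C	0.51625	-1.1750503	0.0063278981	2.2250739e-308	50000
rs66	1	330000	G	T	0.52375	-0.56543912	0.0063317023	2.2250739e-308	50000
rs67	1	335000	T	G	0.50375	-0.41109763	0.0063247332	2.2250739e-308	50000
rs68	1	340000	G	T	0.47625	0.036282727	0.0063317023	1.0023701e-08	50000
rs69	1	345000	T	G	0.50875	0.074624021	0.006325524	4.0309949e-32	50000
rs70	1	350000	T	C	0.51625	-0.018025079	0.0063278981	0.0043924514	50000
rs71	1	355000	T	C	0.1775	-1.2452197	0.008276236	2.2250739e-308	50000
rs72	1	360000	G	T	0.1725	-0.67184426	0.0083699227	2.2250739e-308	50000
rs73	1	365000	T	C	0.18	-0.5586908	0.00823108	2.2250739e-308	50000
rs74	1	370000	C	A	0.18625	-0.2157679	0.0081228112	1.8076701e-155	50000
rs75	1	375000	T	G	0.19375	-0.017456091	0.0080010002	0.029128828	50000
rs76	1	380000	G	A	0.19625	-0.025177382	0.0079622292	0.0015663462	50000
rs77	1	385000	T	G	0.19375	0.020129015	0.0080010002	0.011875839	50000
rs78	1	390000	G	C	0.19125	-0.087314537	0.008040668	1.8049018e-27	50000
rs79	1	395000	T	C	0.18625	-0.3343804	0.0081228112	2.2250739e-308	50000
rs80	1	400000	G	A	0.2	-0.4971447	0.0079056942	2.2250739e-308	50000
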