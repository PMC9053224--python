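variant_id	chrom	pos	effect_allele	other_allele	freq	beta	se	pval	n
rs1	1	5000	A	C	0.37375	0.23854951	0.0065363535	1.2923925e-291	50000
rs2	1	10000	G	A	0.37	0.29343409	0.0065498124	2.2250739e-308	50000
rs3	1	15000	C	A	0.38	0.21435745	0.0065149691	2.0377074e-237	50000
rs4	1	20000	A	C	0.39625	0.11317099	0.0064652718	1.3251347e-68	50000
rs5	1	25000	T	G	0.425	0.11693141	0.0063969302	1.2096722e-74	50000
rs6	1	30000	C	A	0.415	0.071466225	0.006417975	8.4438195e-29	50000
rs7	1	35000	T	C	0.39625	0.06877513	0.0064652718	1.9914296e-26	50000
rs8	1	40000	C	A	0.4075	0.074916403	0.0064356441	2.554402e-31	50000
rs9	1	45000	C	A	0.40625	0.08561222	0.0064387491	2.4286556e-40	50000
rs10	1	50000	G	T	0.3825	-0.11379777	0.0065067751	1.7341289e-68	50000
rs11	1	55000	T	A	0.0975	-1.0170039	0.010660414	2.2250739e-308	50000
rs12	1	60000	T	G	0.09375	-0.64369057	0.010849016	2.2250739e-308	50000
rs13	1	65000	T	A	0.10375	-0.60398205	0.010370301	2.2250739e-308	50000
rs14	1	70000	G	A	0.0975	-0.26938479	0.010660414	6.8915704e-141	50000
rs15	1	75000	G	T	0.09	0.14467226	0.011049892	3.6277809e-39	50000
rs16	1	80000	A	C	0.09625	0.082088171	0.010721992	1.9173012e-14	50000
rs17	1	85000	G	T	0.08625	0.3881282	0.011264366	3.625601e-260	50000
rs18	1	90000	G	T	0.10875	0.5034665	0.010157471	2.2250739e-308	50000
rs19	1	95000	G	A	0.11375	0.27349439	0.0099596981	5.2619308e-166	50000
rs20	1	100000	C	A	0.105	0.092896226	0.010315584	2.1483105e-19	50000
rs21	1	105000	T	C	0.125	0.18134094	0.0095618289	3.3146516e-80	50000
rs22	1	110000	C	A	0.13625	0.12688365	0.0092180214	4.1539035e-43	50000
rs23	1	115000	G	T	0.12	-0.020768547	0.0097312368	0.032825226	50000
rs24	1	120000	G	T	0.13375	0.21784194	0.0092903373	1.3781329e-121	50000
rs25	1	125000	G	A	0.13375	0.23477124	0.0092903373	6.7466883e-141	50000
rs26	1	130000	T	A	0.1275	0.77478974	0.0094811756	2.2250739e-308	50000
rs27	1	135000	A	C	0.13375	1.3069372	0.0092903373	2.2250739e-308	50000
rs28	1	140000	C	A	0.125	0.17784116	0.0095618289	3.2691057e-77	50000
rs29	1	145000	T	C	0.12125	-1.5823837	0.0096878288	2.2250739e-308	50000
rs30	1	150000	T	G	0.1325	-0.7969237	0.0093273295	2.2250739e-308	50000
rs31	1	155000	T	C	0.1225	-0.075785362	0.0096451368	3.9229786e-15	50000
rs32	1	160000	G	A	0.1325	-0.13980119	0.0093273295	8.7512251e-51	50000
rs33	1	165000	C	A	0.1025	-0.12085353	0.010426075	4.5525281e-31	50000
rs34	1	170000	G	T	0.12125	0.040265282	0.0096878288	3.234782e-05	50000
rs35	1	175000	G	A	0.13	-0.36162492	0.009403049	2.2250739e-308	50000
rs36	1	180000	G	A	0.11625	-0.21699982	0.0098659476	3.2275384e-107	50000
rs37	1	185000	T	G	0.12875	-0.26779917	0.0094418041	5.7645271e-177	50000
rs38	1	190000	T	A	0.12875	-0.13673331	0.0094418041	1.58152e-47	50000
rs39	1	195000	A	C	0.1225	-0.015413505	0.0096451368	0.11002968	50000
rs40	1	200000	C	A	0.1175	0.048477652	0.0098202764	7.9542936e-07	50000
rs41	1	205000	T	C	0.25375	-0.038218647	0.007266994	1.4467564e-07	50000
rs42	1	210000	G	A	0.24875	-0.2625459	0.0073152001	4.3034026e-282	50000
rs43	1	215000	T	G	0.24875	-0.29009451	0.0073152001	2.2250739e-308	50000
rs44	1	220000	T	C	0.235	-0.64590498	0.0074582228	2.2250739e-308	50000
rs45	1	225000	G	A	0.23625	-0.13848605	0.0074445505	3.0758828e-77	50000
rs46	1	230000	G	A	0.22875	-0.10559432	0.0075287324	1.0882544e-44	50000
rs47	1	235000	A	C	0.2475	-0.15830271	0.007327556	1.6560038e-103	50000
rs48	1	240000	T	G	0.2675	-0.45408591	0.0071438823	2.2250739e-308	50000
rs49	1	245000	C	A	0.2375	-1.3334162	0.0074310172	2.2250739e-308	50000
rs50	1	250000	G	C	0.225	-0.43405972	0.0075728245	2.2250739e-308	50000
rs51	1	255000	C	A	0.25625	-0.18829445	0.0072436019	5.7013539e-149	50000
rs52	1	260000	T	C	0.22875	-0.12977806	0.0075287324	1.3842764e-66	50000
rs53	1	265000	G	C	0.25375	0.0015964003	0.007266994	0.82612177	50000
rs54	1	270000	A	C	0.25875	0.22177274	0.0072206695	3.7472508e-207	50000
rs55	1	275000	G	T	0.27375	0.84171952	0.0070921819	2.2250739e-308	50000
rs56	1	280000	G	T	0.25875	1.7446565	0.0072206695	2.2250739e-308	50000
rs57	1	285000	G	T	0.23	0.45427919	0.0075143379	2.2250739e-308	50000
rs58	1	290000	T	G	0.25125	0.39377602	0.0072908564	2.2250739e-308	50000
rs59	1	295000	A	C	0.275	0.25273556	0.0070821423	6.4454989e-279	50000
rs60	1	300000	T	G	0.2875	0.027637847	0.0069869662	7.6333498e-05	50000
rs61	1	305000	A	C	0.505	-0.066442053	0.0063248716	8.2022128e-26	50000
rs62	1	310000	T	G	0.515	0.088166059	0.0063274033	3.9365669e-44	50000
rs63	1	315000	G	A	0.51875	-0.048089164	0.006329007	3.0024011e-14	50000
rs64	1	320000	T	G	0.49375	0.039926075	0.0063250495	2.7478786e-10	50000
rs65	1	325000	A	C	0.51625	-0.042109265	0.0063278981	2.8418313e-11	50000
rs66	1	330000	G	T	0.52375	0.076659078	0.0063317023	9.6760572e-34	50000
rs67	1	335000	T	G	0.50375	-0.057757653	0.0063247332	6.72267e-20	50000
rs68	1	340000	G	T	0.47625	-0.017702642	0.0063317023	0.005175956	50000
rs69	1	345000	T	G	0.50875	0.0074334799	0.006325524	0.23993215	50000
rs70	1	350000	T	C	0.51625	0.013467758	0.0063278981	0.033311012	50000
rs71	1	355000	T	C	0.1775	0.035300609	0.008276236	1.9963595e-05	50000
rs72	1	360000	G	T	0.1725	0.32374406	0.0083699227	2.2250739e-308	50000
rs73	1	365000	T	C	0.18	0.019177532	0.00823108	0.019811833	50000
rs74	1	370000	C	A	0.18625	-0.028618647	0.0081228112	0.00042629851	50000
rs75	1	375000	T	G	0.19375	-0.034484297	0.0080010002	1.6325583e-05	50000
rs76	1	380000	G	A	0.19625	0.05513573	0.0079622292	4.3702385e-12	50000
rs77	1	385000	T	G	0.19375	0.29315271	0.0080010002	6.7232994e-294	50000
rs78	1	390000	G	C	0.19125	0.2187301	0.008040668	5.989175e-163	50000
rs79	1	395000	T	C	0.18625	0.10137632	0.0081228112	9.5448311e-36	50000
rs80	1	400000	G	A	0.2	0.02652	0.0079056942	0.00079495863	50000
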