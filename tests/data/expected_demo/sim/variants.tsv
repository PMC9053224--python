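variant_id	chrom	pos	ref	alt	imputation_r2
rs1	1	5000	C	A	0.825702
rs2	1	10000	A	G	0.888024
rs3	1	15000	A	C	0.834913
rs4	1	20000	C	A	0.830802
rs5	1	25000	G	T	0.959308
rs6	1	30000	A	C	0.914495
rs7	1	35000	C	T	0.971873
rs8	1	40000	A	C	0.915464
rs9	1	45000	A	C	0.989736
rs10	1	50000	T	G	0.898047
rs11	1	55000	A	T	0.817049
rs12	1	60000	G	T	0.341473
rs13	1	65000	A	T	0.997352
rs14	1	70000	A	G	0.831634
rs15	1	75000	T	G	0.951199
rs16	1	80000	C	A	0.932979
rs17	1	85000	T	G	0.949612
rs18	1	90000	T	G	0.847086
rs19	1	95000	A	G	0.686758
rs20	1	100000	A	C	0.898025
rs21	1	105000	C	T	0.917812
rs22	1	110000	A	C	0.946863
rs23	1	115000	T	G	0.817849
rs24	1	120000	T	G	0.724812
rs25	1	125000	A	G	0.690557
rs26	1	130000	A	T	0.942619
rs27	1	135000	C	A	0.970161
rs28	1	140000	A	C	0.990128
rs29	1	145000	C	T	0.810702
rs30	1	150000	G	T	0.815451
rs31	1	155000	C	T	0.848751
rs32	1	160000	A	G	0.847529
rs33	1	165000	A	C	0.980904
rs34	1	170000	T	G	0.877315
rs35	1	175000	A	G	0.99066
rs36	1	180000	A	G	0.942702
rs37	1	185000	G	T	0.927126
rs38	1	190000	A	T	0.826584
rs39	1	195000	C	A	0.732684
rs40	1	200000	A	C	0.882304
rs41	1	205000	C	T	0.968114
rs42	1	210000	A	G	0.811622
rs43	1	215000	G	T	0.921678
rs44	1	220000	C	T	0.948025
rs45	1	225000	A	G	0.885302
rs46	1	230000	A	G	0.915811
rs47	1	235000	C	A	0.996376
rs48	1	240000	G	T	0.896506
rs49	1	245000	A	C	0.996612
rs50	1	250000	C	G	0.855508
rs51	1	255000	A	C	0.802654
rs52	1	260000	C	T	0.995889
rs53	1	265000	C	G	0.994332
rs54	1	270000	C	A	0.955949
rs55	1	275000	T	G	0.902973
rs56	1	280000	T	G	0.973527
rs57	1	285000	T	G	0.834106
rs58	1	290000	G	T	0.961806
rs59	1	295000	C	A	0.9951
rs60	1	300000	G	T	0.851263
rs61	1	305000	C	A	0.945738
rs62	1	310000	G	T	0.876446
rs63	1	315000	A	G	0.80579
rs64	1	320000	G	T	0.486551
rs65	1	325000	C	A	0.80127
rs66	1	330000	T	G	0.478698
rs67	1	335000	G	T	0.93226
rs68	1	340000	T	G	0.488467
rs69	1	345000	G	T	0.833898
rs70	1	350000	C	T	0.908714
rs71	1	355000	C	T	0.815028
rs72	1	360000	T	G	0.873699
rs73	1	365000	C	T	0.955042
rs74	1	370000	A	C	0.94098
rs75	1	375000	G	T	0.859906
rs76	1	380000	A	G	0.848768
rs77	1	385000	G	T	0.863556
rs78	1	390000	C	G	0.965118
rs79	1	395000	C	T	0.834902
rs80	1	400000	A	G	0.94179
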