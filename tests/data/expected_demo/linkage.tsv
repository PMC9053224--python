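node_a	node_b	height	size
21	37	0.14855848	2
7	31	0.1970578	2
29	36	0.22597742	2
23	35	0.24364055	2
14	18	0.288548	2
3	27	0.2915198	2
28	32	0.2942237	2
11	19	0.30790375	2
4	16	0.33212941	2
15	38	0.35336997	2
13	33	0.3940321	2
1	17	0.43646114	2
6	34	0.44908814	2
20	39	0.46423199	2
10	22	0.47164781	2
2	25	0.48055731	2
0	8	0.49877222	2
43	47	0.52519584	4
9	26	0.56112355	2
30	42	0.60270818	3
5	51	0.61731964	3
24	41	0.62061958	3
46	56	0.63847124	4
12	48	0.6404344	3
40	60	0.69278191	5
49	55	0.77899504	4
44	50	0.79025263	4
53	58	0.82505805	4
61	63	0.8808815	6
52	54	0.97323285	4
59	65	0.99221301	7
45	57	1.0932008	6
62	68	1.2458745	10
69	70	1.3029232	11
66	73	1.3195126	15
67	72	1.4571644	14
64	75	1.5450073	19
71	74	1.6800797	21
76	77	1.9244754	40
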