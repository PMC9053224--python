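side_effect	reduction	full_loglik	reduced_loglik	delta_aic	lrt_stat	df	pvalue	full_converged	reduced_converged
nausea	ssri_only	-864.88842	-865.78095	-4.2149355	1.7850645	3	0.61819045	True	True
nausea	snri_only	-864.88842	-870.65205	1.5272562	11.527256	5	0.0418722	True	True
nausea	common_only	-864.88842	-871.22077	-3.3352953	12.664705	8	0.12391864	True	True
sweating	ssri_only	-791.56243	-794.49935	-0.12615971	5.8738403	3	0.11791212	False	True
sweating	snri_only	-791.56243	-793.34818	-6.4284948	3.5715052	5	0.61259667	False	True
sweating	common_only	-791.56243	-796.08697	-6.9509265	9.0490735	8	0.33817311	False	True
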