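side_effect	model_class	medication	drug_class	general_loading	class_loading	threshold	loglik	aic	converged
nausea	full	sertraline	SSRI	0.58779941	0.163031	0.42905478	-864.88842	1785.7768	True
nausea	full	escitalopram	SSRI	0.44667313	0.89468258	0.46203693	-864.88842	1785.7768	True
nausea	full	venlafaxine	SNRI	0.69281181	0.12398419	0.5282953	-864.88842	1785.7768	True
nausea	full	fluoxetine	SSRI	0.54766169	0.36514382	0.44744985	-864.88842	1785.7768	True
nausea	full	citalopram	SSRI	0.34197197	0.59352687	0.45545948	-864.88842	1785.7768	True
nausea	full	desvenlafaxine	SNRI	0.43516438	0.22446573	0.59589468	-864.88842	1785.7768	True
nausea	full	duloxetine	SNRI	0.64499119	0.76399887	0.68028007	-864.88842	1785.7768	True
nausea	full	mirtazapine	other	0.77216729	0	0.31705049	-864.88842	1785.7768	True
nausea	full	amitriptyline	other	0.81061427	0	0.52988622	-864.88842	1785.7768	True
nausea	full	paroxetine	SSRI	0.44738598	0.46695772	0.28493522	-864.88842	1785.7768	True
nausea	ssri_only	sertraline	SSRI	0.58654549	0.15422887	0.42263392	-865.78095	1781.5619	True
nausea	ssri_only	escitalopram	SSRI	0.44816306	0.89390087	0.46501198	-865.78095	1781.5619	True
nausea	ssri_only	venlafaxine	SNRI	0.70928795	0	0.52260759	-865.78095	1781.5619	True
nausea	ssri_only	fluoxetine	SSRI	0.5511402	0.3464651	0.44555039	-865.78095	1781.5619	True
nausea	ssri_only	citalopram	SSRI	0.3565712	0.58122519	0.45127471	-865.78095	1781.5619	True
nausea	ssri_only	desvenlafaxine	SNRI	0.46631726	0	0.58432411	-865.78095	1781.5619	True
nausea	ssri_only	duloxetine	SNRI	0.49530243	0	0.61578713	-865.78095	1781.5619	True
nausea	ssri_only	mirtazapine	other	0.76815881	0	0.31012237	-865.78095	1781.5619	True
nausea	ssri_only	amitriptyline	other	0.74295821	0	0.52777906	-865.78095	1781.5619	True
nausea	ssri_only	paroxetine	SSRI	0.44951369	0.46602855	0.27885051	-865.78095	1781.5619	True
nausea	snri_only	sertraline	SSRI	0.58918924	0	0.42429144	-870.65205	1787.3041	True
nausea	snri_only	escitalopram	SSRI	0.73585729	0	0.58290676	-870.65205	1787.3041	True
nausea	snri_only	venlafaxine	SNRI	0.63597537	0.12377259	0.51728827	-870.65205	1787.3041	True
nausea	snri_only	fluoxetine	SSRI	0.64310457	0	0.4418355	-870.65205	1787.3041	True
nausea	snri_only	citalopram	SSRI	0.58537233	0	0.46969742	-870.65205	1787.3041	True
nausea	snri_only	desvenlafaxine	SNRI	0.42780191	0.19273506	0.58626868	-870.65205	1787.3041	True
nausea	snri_only	duloxetine	SNRI	0.58312859	0.81193702	0.61493737	-870.65205	1787.3041	True
nausea	snri_only	mirtazapine	other	0.65767265	0	0.31537651	-870.65205	1787.3041	True
nausea	snri_only	amitriptyline	other	0.66407457	0	0.5078472	-870.65205	1787.3041	True
nausea	snri_only	paroxetine	SSRI	0.62609724	0	0.26887568	-870.65205	1787.3041	True
nausea	common_only	sertraline	SSRI	0.58390678	0	0.42344266	-871.22077	1782.4415	True
nausea	common_only	escitalopram	SSRI	0.7420097	0	0.58278756	-871.22077	1782.4415	True
nausea	common_only	venlafaxine	SNRI	0.63417142	0	0.51576203	-871.22077	1782.4415	True
nausea	common_only	fluoxetine	SSRI	0.63970096	0	0.44467747	-871.22077	1782.4415	True
nausea	common_only	citalopram	SSRI	0.59192877	0	0.47107967	-871.22077	1782.4415	True
nausea	common_only	desvenlafaxine	SNRI	0.44968894	0	0.57987455	-871.22077	1782.4415	True
nausea	common_only	duloxetine	SNRI	0.48807266	0	0.61489599	-871.22077	1782.4415	True
nausea	common_only	mirtazapine	other	0.65742512	0	0.31376364	-871.22077	1782.4415	True
nausea	common_only	amitriptyline	other	0.64748604	0	0.50854044	-871.22077	1782.4415	True
nausea	common_only	paroxetine	SSRI	0.62279551	0	0.26849891	-871.22077	1782.4415	True
sweating	full	sertraline	SSRI	0.5755902	0.28723192	0.52239706	-791.56243	1639.1249	False
sweating	full	escitalopram	SSRI	0.70645294	-0.70774761	0.7243977	-791.56243	1639.1249	False
sweating	full	venlafaxine	SNRI	0.49667609	0.5172109	0.58140765	-791.56243	1639.1249	False
sweating	full	fluoxetine	SSRI	0.82246264	0.33555287	0.69493491	-791.56243	1639.1249	False
sweating	full	citalopram	SSRI	0.44029981	0.075566622	0.88554925	-791.56243	1639.1249	False
sweating	full	desvenlafaxine	SNRI	0.28818235	0.87696398	0.90496259	-791.56243	1639.1249	False
sweating	full	duloxetine	SNRI	0.31216714	0.43487079	0.59495235	-791.56243	1639.1249	False
sweating	full	mirtazapine	other	0.23797964	0	0.76012851	-791.56243	1639.1249	False
sweating	full	amitriptyline	other	0.70857238	0	0.69620647	-791.56243	1639.1249	False
sweating	full	paroxetine	SSRI	0.69156084	0.32070887	0.45513371	-791.56243	1639.1249	False
sweating	ssri_only	sertraline	SSRI	0.59652064	0.17340671	0.51679221	-794.49935	1638.9987	True
sweating	ssri_only	escitalopram	SSRI	0.44098784	0.06508569	0.68891054	-794.49935	1638.9987	True
sweating	ssri_only	venlafaxine	SNRI	0.59012309	0	0.57074776	-794.49935	1638.9987	True
sweating	ssri_only	fluoxetine	SSRI	0.69900151	0.6089234	0.68944515	-794.49935	1638.9987	True
sweating	ssri_only	citalopram	SSRI	0.22855392	0.77907017	0.86324331	-794.49935	1638.9987	True
sweating	ssri_only	desvenlafaxine	SNRI	0.58327107	0	0.88976138	-794.49935	1638.9987	True
sweating	ssri_only	duloxetine	SNRI	0.47511728	0	0.57205676	-794.49935	1638.9987	True
sweating	ssri_only	mirtazapine	other	0.24124855	0	0.75400294	-794.49935	1638.9987	True
sweating	ssri_only	amitriptyline	other	0.6527412	0	0.70836762	-794.49935	1638.9987	True
sweating	ssri_only	paroxetine	SSRI	0.75652485	0.13589016	0.45328523	-794.49935	1638.9987	True
sweating	snri_only	sertraline	SSRI	0.61548823	0	0.51952499	-793.34818	1632.6964	True
sweating	snri_only	escitalopram	SSRI	0.45481451	0	0.68737121	-793.34818	1632.6964	True
sweating	snri_only	venlafaxine	SNRI	0.49462812	0.4891639	0.57813045	-793.34818	1632.6964	True
sweating	snri_only	fluoxetine	SSRI	0.8522494	0	0.6830567	-793.34818	1632.6964	True
sweating	snri_only	citalopram	SSRI	0.43295457	0	0.88652055	-793.34818	1632.6964	True
sweating	snri_only	desvenlafaxine	SNRI	0.33368224	0.85440419	0.90297897	-793.34818	1632.6964	True
sweating	snri_only	duloxetine	SNRI	0.32992041	0.4235207	0.59509391	-793.34818	1632.6964	True
sweating	snri_only	mirtazapine	other	0.22920959	0	0.75556124	-793.34818	1632.6964	True
sweating	snri_only	amitriptyline	other	0.72232432	0	0.68715184	-793.34818	1632.6964	True
sweating	snri_only	paroxetine	SSRI	0.76183371	0	0.44971585	-793.34818	1632.6964	True
sweating	common_only	sertraline	SSRI	0.63132766	0	0.51632696	-796.08697	1632.1739	True
sweating	common_only	escitalopram	SSRI	0.43680909	0	0.68822544	-796.08697	1632.1739	True
sweating	common_only	venlafaxine	SNRI	0.56086274	0	0.56778925	-796.08697	1632.1739	True
sweating	common_only	fluoxetine	SSRI	0.82612397	0	0.6781454	-796.08697	1632.1739	True
sweating	common_only	citalopram	SSRI	0.40292481	0	0.89154007	-796.08697	1632.1739	True
sweating	common_only	desvenlafaxine	SNRI	0.51921654	0	0.88826607	-796.08697	1632.1739	True
sweating	common_only	duloxetine	SNRI	0.41494334	0	0.57774131	-796.08697	1632.1739	True
sweating	common_only	mirtazapine	other	0.22441252	0	0.75409381	-796.08697	1632.1739	True
sweating	common_only	amitriptyline	other	0.65928899	0	0.69344614	-796.08697	1632.1739	True
sweating	common_only	paroxetine	SSRI	0.7879139	0	0.45185861	-796.08697	1632.1739	True
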