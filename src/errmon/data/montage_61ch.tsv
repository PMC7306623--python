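label	x	y	z
Fp1	-0.329990863	0.940726244	-0.078359196
Fpz	0.001272324	0.999810842	-0.019407753
Fp2	0.330898906	0.940401659	-0.078425975
AF7	-0.620075886	0.775350115	-0.119741786
AF3	-0.389395025	0.887814926	0.245267552
AF4	0.404394580	0.880143052	0.248622671
AF8	0.620325912	0.775158951	-0.119684432
F7	-0.847627021	0.512395082	-0.137766881
F5	-0.784678906	0.584686557	0.205962724
F3	-0.595220302	0.629189362	0.499833511
F1	-0.314606189	0.651404083	0.690431507
Fz	0.003525726	0.660785686	0.750566350
F2	0.335603691	0.654986760	0.677024746
F4	0.606622648	0.635511893	0.477633329
F6	0.791456065	0.580703568	0.190737157
F8	0.846108033	0.514566841	-0.139004182
FT7	-0.976103764	0.170632968	-0.134557913
FC5	-0.929019417	0.224308880	0.294293134
FC3	-0.708119254	0.267285988	0.653548256
FC1	-0.375357157	0.286638518	0.881445043
FCz	0.004052678	0.295141818	0.955444861
FC2	0.386023312	0.293399735	0.874587101
FC4	0.717488266	0.273237817	0.640743072
FC6	0.929583287	0.233005636	0.285627880
FT8	0.973730285	0.183483338	-0.134845085
T7	-0.976570504	-0.185874352	-0.108447108
C5	-0.927952306	-0.159047452	0.337058490
C3	-0.706876497	-0.125801933	0.696059977
C1	-0.371707597	-0.102635419	0.922658893
Cz	0.003982593	-0.091066165	0.995836880
C2	0.390043574	-0.099644786	0.915388949
C4	0.720987738	-0.117092201	0.682983234
C6	0.934161956	-0.143011260	0.326939167
T8	0.978883568	-0.172815493	-0.109186836
TP7	-0.876639471	-0.475590518	-0.072917052
CP5	-0.818335172	-0.478615682	0.318205242
CP3	-0.618605595	-0.457546340	0.638731919
CP1	-0.326425186	-0.434692191	0.839338607
CPz	0.003503530	-0.429704620	0.902962715
CP2	0.351645472	-0.431250748	0.830884020
CP4	0.637648213	-0.446439328	0.627771203
CP6	0.831487536	-0.460055548	0.311411900
TP8	0.880319532	-0.468673052	-0.073369565
P7	-0.701949583	-0.711818740	-0.024101132
P5	-0.637047976	-0.722449449	0.268768805
P3	-0.480959788	-0.714878207	0.507569534
P1	-0.251074862	-0.706413913	0.661770955
Pz	0.002804459	-0.700596520	0.713552136
P2	0.275925627	-0.695760096	0.663161321
P4	0.498503987	-0.703518853	0.506512584
P6	0.642647001	-0.718534739	0.265918523
P8	0.706832268	-0.706954176	-0.024575139
PO7	-0.489979418	-0.871377008	0.024945524
PO3	-0.321642333	-0.888450237	0.327417754
POz	0.001890824	-0.896106584	0.443834896
PO4	0.324496489	-0.889716023	0.321103452
PO8	0.495193240	-0.868443367	0.024285254
O1	-0.252328673	-0.964665999	0.075827111
Oz	0.000929002	-0.991960262	0.126546335
O2	0.256398374	-0.963609607	0.075606874
Iz	0.000037255	-0.981578618	-0.191058671
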