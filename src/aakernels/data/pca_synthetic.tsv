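# synthetic 5-component descriptor set: PCA of standardized BLOSUM50 rows (stand-in)
A	-0.591721	2.654623	0.013045	-0.129702	-1.554581
C	1.410630	2.213241	1.639300	-1.443123	3.285576
D	-3.506779	0.061986	1.054190	0.650654	1.002306
E	-2.804107	-1.037283	-0.891786	0.867863	1.011818
F	4.314241	-1.883180	1.068312	-0.837977	0.161522
G	-1.713670	1.134420	3.400635	-0.168805	-1.344849
H	-1.701451	-2.786782	-0.085089	-1.800428	0.040136
I	4.264889	1.520630	-0.734653	0.784471	0.135489
K	-2.901804	-0.978014	-1.513835	0.544710	0.317659
L	4.084619	0.325258	-0.987200	0.543581	0.367679
M	3.144976	0.071625	-1.954864	0.096123	-0.586530
N	-3.128128	0.515900	0.344224	-1.262032	-0.035216
P	-1.617463	0.730317	1.558115	3.038511	0.142495
Q	-2.592688	-1.428591	-1.824594	0.576450	-0.122992
R	-2.071939	-1.876750	-1.489574	0.110684	0.522403
S	-2.449002	2.167518	-0.120629	-1.173822	-1.087369
T	-0.656512	2.519247	-1.124903	-0.714465	-0.733469
V	3.550948	2.098903	-0.941161	0.493234	0.035016
W	2.751376	-3.251135	2.305503	1.179253	-0.719999
Y	2.213585	-2.771933	0.284964	-1.355179	-0.837095
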