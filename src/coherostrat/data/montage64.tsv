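label	x	y	roi
Fp1	-0.545911	1.556265	Frontal
Fp2	0.547439	1.555799	Frontal
Fpz	0.002024	1.590204	Frontal
AF3	-0.531401	1.211587	Frontal
AF4	0.550913	1.199032	Frontal
AF7	-1.056039	1.320483	Frontal
AF8	1.056421	1.320103	Frontal
F1	-0.351709	0.728227	Frontal
F2	0.377157	0.736085	Frontal
F3	-0.719792	0.760871	Frontal
F4	0.740767	0.776044	Frontal
F5	-1.093230	0.814597	Frontal
F6	1.111736	0.815698	Frontal
Fz	0.003852	0.721867	Frontal
FC1	-0.390932	0.298532	Central
FC2	0.403016	0.306315	Central
FC3	-0.803219	0.303182	Central
FC4	0.818020	0.311523	Central
FC5	-1.236548	0.298561	Central
FC6	1.242691	0.311488	Central
C1	-0.381597	-0.105366	Central
C2	0.401431	-0.102554	Central
C3	-0.788511	-0.140330	Central
C4	0.808366	-0.131283	Central
C5	-1.209370	-0.207281	Central
C6	1.223479	-0.187303	Central
Cz	0.003988	-0.091193	Central
CP1	-0.345113	-0.459579	Parietal
CP2	0.372914	-0.457335	Parietal
CP3	-0.705852	-0.522077	Parietal
CP4	0.730799	-0.511657	Parietal
CP5	-1.076380	-0.629537	Parietal
CP6	1.097349	-0.607155	Parietal
CPz	0.003621	-0.444167	Parietal
P1	-0.283865	-0.798672	Parietal
P2	0.311790	-0.786193	Parietal
P3	-0.579665	-0.861589	Parietal
P4	0.601085	-0.848288	Parietal
P5	-0.858927	-0.974073	Parietal
P6	0.867737	-0.970205	Parietal
P7	-1.119865	-1.135609	Parietal
P8	1.128002	-1.128197	Parietal
Pz	0.003107	-0.776235	Parietal
O1	-0.378294	-1.446239	Occipital
O2	0.384446	-1.444845	Occipital
Oz	0.001352	-1.443909	Occipital
PO3	-0.421159	-1.163338	Occipital
PO4	0.426212	-1.168604	Occipital
PO7	-0.757670	-1.347436	Occipital
PO8	0.766047	-1.343451	Occipital
POz	0.002344	-1.110920	Occipital
F7	-1.462543	0.884115	Temporal
F8	1.461244	0.888666	Temporal
FT7	-1.680283	0.293731	Temporal
FT8	1.676548	0.315918	Temporal
T7	-1.649839	-0.314020	Temporal
T8	1.654614	-0.292111	Temporal
TP7	-1.444847	-0.783852	Temporal
TP8	1.451361	-0.772690	Temporal
TP9	-1.765666	-0.959241	Temporal
TP10	1.762416	-0.962094	Temporal
AFz	0.003315	1.157555	
FT9	-2.073674	0.359292	
FT10	2.075457	0.354443	
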