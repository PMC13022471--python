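label	x	y	roi
Fp1	-0.545911	1.556265	Frontal
Fp2	0.547439	1.555799	Frontal
F3	-0.719792	0.760871	Frontal
F4	0.740767	0.776044	Frontal
Fz	0.003852	0.721867	Frontal
C3	-0.788511	-0.140330	Central
C4	0.808366	-0.131283	Central
Cz	0.003988	-0.091193	Central
P3	-0.579665	-0.861589	Parietal
P4	0.601085	-0.848288	Parietal
P7	-1.119865	-1.135609	Parietal
P8	1.128002	-1.128197	Parietal
Pz	0.003107	-0.776235	Parietal
O1	-0.378294	-1.446239	Occipital
O2	0.384446	-1.444845	Occipital
F7	-1.462543	0.884115	Temporal
F8	1.461244	0.888666	Temporal
T7	-1.649839	-0.314020	Temporal
T8	1.654614	-0.292111	Temporal
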