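number,name,side,role,gpa_excluded,ux,uy,uz
1,Glabella,midline,LM,0,1.000,0.000,0.150
2,Nasion,midline,LM,0,1.000,0.000,0.050
3,Rhinion,midline,LM,0,1.000,0.000,-0.120
4,Nasospinale,midline,LM,0,1.000,0.000,-0.250
5,Subspinale,midline,LM,0,1.000,0.000,-0.330
6,Prosthion,midline,LM,0,1.000,0.000,-0.420
7,Staphylion,midline,LM,0,0.550,0.000,-0.950
8,Hormion,midline,LM,0,0.300,0.000,-1.000
9,Basion,midline,LM,0,0.050,0.000,-1.000
10,Opisthion,midline,LM,0,-0.220,0.000,-1.000
11,Metopion,midline,LM,0,0.600,0.000,0.850
12,Vertex,midline,LM,0,0.050,0.000,1.000
13,Euryon_L,L,LM,1,0.000,1.000,0.050
14,Euryon_R,R,LM,1,0.000,-1.000,0.050
15,Frontotemporale_L,L,LM,0,0.550,0.550,0.450
16,Frontotemporale_R,R,LM,0,0.550,-0.550,0.450
17,Zygion_L,L,LM,0,0.450,0.950,-0.120
18,Zygion_R,R,LM,0,0.450,-0.950,-0.120
19,Zygomaxillare_L,L,LM,0,0.700,0.550,-0.300
20,Zygomaxillare_R,R,LM,0,0.700,-0.550,-0.300
21,Jugale_L,L,LM,0,0.520,0.800,-0.050
22,Jugale_R,R,LM,0,0.520,-0.800,-0.050
23,Orbitale_L,L,LM,0,0.900,0.350,-0.150
24,Orbitale_R,R,LM,0,0.900,-0.350,-0.150
25,Dacryon_L,L,LM,0,0.950,0.150,0.020
26,Dacryon_R,R,LM,0,0.950,-0.150,0.020
27,Ectoconchion_L,L,LM,0,0.750,0.500,0.000
28,Ectoconchion_R,R,LM,0,0.750,-0.500,0.000
29,Maxillofrontale_L,L,LM,0,0.970,0.120,0.000
30,Maxillofrontale_R,R,LM,0,0.970,-0.120,0.000
31,FrontomalareTemporale_L,L,LM,0,0.700,0.520,0.120
32,FrontomalareTemporale_R,R,LM,0,0.700,-0.520,0.120
33,Supraorbitale_L,L,LM,0,0.900,0.300,0.120
34,Supraorbitale_R,R,LM,0,0.900,-0.300,0.120
35,Infraorbitale_L,L,LM,0,0.920,0.300,-0.180
36,Infraorbitale_R,R,LM,0,0.920,-0.300,-0.180
37,Alare_L,L,LM,0,0.950,0.180,-0.200
38,Alare_R,R,LM,0,0.950,-0.180,-0.200
39,Ectomolare_L,L,LM,0,0.550,0.400,-0.850
40,Ectomolare_R,R,LM,0,0.550,-0.400,-0.850
41,Endomolare_L,L,LM,0,0.550,0.300,-0.900
42,Endomolare_R,R,LM,0,0.550,-0.300,-0.900
43,Porion_L,L,LM,0,-0.050,0.950,-0.350
44,Porion_R,R,LM,0,-0.050,-0.950,-0.350
45,Mastoidale_L,L,LM,0,-0.120,0.800,-0.620
46,Mastoidale_R,R,LM,0,-0.120,-0.800,-0.620
47,Sphenobasion,midline,LM,0,0.180,0.000,-1.000
48,Bregma,midline,LM,0,0.250,0.000,1.000
49,Lambda,midline,LM,0,-0.550,0.000,0.800
50,Opisthocranion,midline,LM,0,-1.000,0.000,0.050
51,Inion,midline,LM,0,-0.950,0.000,-0.300
52,Sphenion_L,L,LM,0,0.450,0.800,0.280
53,Sphenion_R,R,LM,0,0.450,-0.800,0.280
54,Krotaphion_L,L,LM,0,0.300,0.880,0.250
55,Krotaphion_R,R,LM,0,0.300,-0.880,0.250
56,Stephanion_L,L,LM,0,0.350,0.620,0.700
57,Stephanion_R,R,LM,0,0.350,-0.620,0.700
58,Entomion_L,L,LM,0,-0.350,0.850,0.050
59,Entomion_R,R,LM,0,-0.350,-0.850,0.050
60,Asterion_L,L,LM,0,-0.550,0.700,-0.250
61,Asterion_R,R,LM,0,-0.550,-0.700,-0.250
62,Auriculare_L,L,LM,0,0.000,0.980,-0.220
63,Auriculare_R,R,LM,0,0.000,-0.980,-0.220
64,CondylionLaterale_L,L,LM,0,-0.050,0.300,-1.000
65,CondylionLaterale_R,R,LM,0,-0.050,-0.300,-1.000
66,ForamenMagnumLaterale_L,L,LM,0,-0.100,0.220,-1.000
67,ForamenMagnumLaterale_R,R,LM,0,-0.100,-0.220,-1.000
68,ParietalBoss_L,L,LM,0,-0.250,0.700,0.600
69,ParietalBoss_R,R,LM,0,-0.250,-0.700,0.600
70,TemporalCrest_L,L,LM,0,0.200,0.850,0.400
71,TemporalCrest_R,R,LM,0,0.200,-0.850,0.400
72,SupramastoidCrest_L,L,LM,0,-0.150,0.900,-0.150
73,SupramastoidCrest_R,R,LM,0,-0.150,-0.900,-0.150
74,Pterion_L,L,LM,0,0.500,0.720,0.350
75,Pterion_R,R,LM,0,0.500,-0.720,0.350
76,Zygoorbitale_L,L,LM,0,0.850,0.400,-0.120
77,Zygoorbitale_R,R,LM,0,0.850,-0.400,-0.120
78,FrontomalareOrbitale_L,L,LM,0,0.780,0.480,0.080
79,FrontomalareOrbitale_R,R,LM,0,0.780,-0.480,0.080
80,Nariale_L,L,LM,0,0.970,0.140,-0.220
81,Nariale_R,R,LM,0,0.970,-0.140,-0.220
82,CaninaFossa_L,L,LM,0,0.880,0.280,-0.350
83,CaninaFossa_R,R,LM,0,0.880,-0.280,-0.350
84,TuberMaxillae_L,L,LM,0,0.620,0.420,-0.650
85,TuberMaxillae_R,R,LM,0,0.620,-0.420,-0.650
86,OccipitalSquama_L,L,LM,0,-0.800,0.420,0.300
87,OccipitalSquama_R,R,LM,0,-0.800,-0.420,0.300
88,Incisivion,midline,LM,0,0.850,0.000,-0.550
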