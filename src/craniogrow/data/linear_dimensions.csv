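index,name,endpoint_a,endpoint_b,kind
1,Maximum cranial breadth,Euryon_L,Euryon_R,distance
2,Maximum cranial length,Glabella,Opisthocranion,distance
3,Cranial circumference,Glabella,Opisthocranion,circumference
4,Basion-bregma height,Basion,Bregma,distance
5,Nasion-basion length,Nasion,Basion,distance
6,Basion-prosthion length,Basion,Prosthion,distance
7,Maximum frontal breadth,Stephanion_L,Stephanion_R,distance
8,Minimum frontal breadth,Frontotemporale_L,Frontotemporale_R,distance
9,Biasterionic breadth,Asterion_L,Asterion_R,distance
10,Biauricular breadth,Auriculare_L,Auriculare_R,distance
11,Biporion breadth,Porion_L,Porion_R,distance
12,Bimastoid breadth,Mastoidale_L,Mastoidale_R,distance
13,Frontal chord,Nasion,Bregma,distance
14,Foramen magnum length,Basion,Opisthion,distance
15,Foramen magnum breadth,ForamenMagnumLaterale_L,ForamenMagnumLaterale_R,distance
16,Upper facial height,Nasion,Prosthion,distance
17,Parietal chord,Bregma,Lambda,distance
18,Occipital chord,Lambda,Opisthion,distance
19,Bizygomatic breadth,Zygion_L,Zygion_R,distance
20,Bijugal breadth,Jugale_L,Jugale_R,distance
21,Bimaxillary breadth,Zygomaxillare_L,Zygomaxillare_R,distance
22,Biorbital breadth,Ectoconchion_L,Ectoconchion_R,distance
23,Interorbital breadth,Dacryon_L,Dacryon_R,distance
24,Nasal breadth,Alare_L,Alare_R,distance
25,Glabella-lambda length,Glabella,Lambda,distance
26,Nasal height,Nasion,Nasospinale,distance
27,Nasal bone length,Rhinion,Nasospinale,distance
28,Nasion-vertex height,Nasion,Vertex,distance
29,Glabella-inion length,Glabella,Inion,distance
30,Lambda-inion chord,Lambda,Inion,distance
31,Orbital breadth (left),Dacryon_L,Ectoconchion_L,distance
32,Orbital breadth (right),Dacryon_R,Ectoconchion_R,distance
33,Orbital height (left),Supraorbitale_L,Infraorbitale_L,distance
34,Orbital height (right),Supraorbitale_R,Infraorbitale_R,distance
35,Cheek height (left),Orbitale_L,Zygomaxillare_L,distance
36,Cheek height (right),Orbitale_R,Zygomaxillare_R,distance
37,Malar length (left),Jugale_L,Zygomaxillare_L,distance
38,Malar length (right),Jugale_R,Zygomaxillare_R,distance
39,Mastoid height (left),Porion_L,Mastoidale_L,distance
40,Mastoid height (right),Porion_R,Mastoidale_R,distance
41,Basion-porion length (left),Basion,Porion_L,distance
42,Nasion-porion length (left),Nasion,Porion_L,distance
43,Maxillo-alveolar breadth,Ectomolare_L,Ectomolare_R,distance
44,Alveolar height,Subspinale,Prosthion,distance
45,Maximum palatal length,Prosthion,Staphylion,distance
46,Bicanine breadth,CaninaFossa_L,CaninaFossa_R,distance
47,Internal palatal width,Endomolare_L,Endomolare_R,distance
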