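roi_id	name	hemisphere	x	y	z
1	Precentral_L	L	-39.0	-6.0	51.0
2	Precentral_R	R	39.0	-6.0	51.0
3	Frontal_Sup_L	L	-20.0	31.0	44.0
4	Frontal_Sup_R	R	20.0	31.0	44.0
5	Frontal_Sup_Orb_L	L	-17.0	47.0	-13.0
6	Frontal_Sup_Orb_R	R	17.0	47.0	-13.0
7	Frontal_Mid_L	L	-34.0	33.0	35.0
8	Frontal_Mid_R	R	34.0	33.0	35.0
9	Frontal_Mid_Orb_L	L	-31.0	50.0	-10.0
10	Frontal_Mid_Orb_R	R	31.0	50.0	-10.0
11	Frontal_Inf_Oper_L	L	-49.0	15.0	21.0
12	Frontal_Inf_Oper_R	R	49.0	15.0	21.0
13	Frontal_Inf_Tri_L	L	-47.0	30.0	14.0
14	Frontal_Inf_Tri_R	R	47.0	30.0	14.0
15	Frontal_Inf_Orb_L	L	-37.0	31.0	-12.0
16	Frontal_Inf_Orb_R	R	37.0	31.0	-12.0
17	Rolandic_Oper_L	L	-48.0	-8.0	14.0
18	Rolandic_Oper_R	R	48.0	-8.0	14.0
19	Supp_Motor_Area_L	L	-6.0	5.0	61.0
20	Supp_Motor_Area_R	R	6.0	5.0	61.0
21	Olfactory_L	L	-9.0	15.0	-12.0
22	Olfactory_R	R	9.0	15.0	-12.0
23	Frontal_Sup_Medial_L	L	-6.0	49.0	31.0
24	Frontal_Sup_Medial_R	R	6.0	49.0	31.0
25	Frontal_Med_Orb_L	L	-6.0	52.0	-7.0
26	Frontal_Med_Orb_R	R	6.0	52.0	-7.0
27	Rectus_L	L	-6.0	37.0	-18.0
28	Rectus_R	R	6.0	37.0	-18.0
29	Insula_L	L	-37.0	7.0	3.0
30	Insula_R	R	37.0	7.0	3.0
31	Cingulum_Ant_L	L	-5.0	35.0	14.0
32	Cingulum_Ant_R	R	5.0	35.0	14.0
33	Cingulum_Mid_L	L	-6.0	-15.0	42.0
34	Cingulum_Mid_R	R	6.0	-15.0	42.0
35	Cingulum_Post_L	L	-6.0	-43.0	25.0
36	Cingulum_Post_R	R	6.0	-43.0	25.0
37	Hippocampus_L	L	-26.0	-21.0	-10.0
38	Hippocampus_R	R	26.0	-21.0	-10.0
39	ParaHippocampal_L	L	-24.0	-16.0	-21.0
40	ParaHippocampal_R	R	24.0	-16.0	-21.0
41	Amygdala_L	L	-24.0	-1.0	-17.0
42	Amygdala_R	R	24.0	-1.0	-17.0
43	Calcarine_L	L	-9.0	-79.0	6.0
44	Calcarine_R	R	9.0	-79.0	6.0
45	Cuneus_L	L	-7.0	-80.0	27.0
46	Cuneus_R	R	7.0	-80.0	27.0
47	Lingual_L	L	-15.0	-68.0	-5.0
48	Lingual_R	R	15.0	-68.0	-5.0
49	Occipital_Sup_L	L	-18.0	-84.0	28.0
50	Occipital_Sup_R	R	18.0	-84.0	28.0
51	Occipital_Mid_L	L	-34.0	-81.0	16.0
52	Occipital_Mid_R	R	34.0	-81.0	16.0
53	Occipital_Inf_L	L	-38.0	-82.0	-8.0
54	Occipital_Inf_R	R	38.0	-82.0	-8.0
55	Fusiform_L	L	-33.0	-40.0	-20.0
56	Fusiform_R	R	33.0	-40.0	-20.0
57	Postcentral_L	L	-43.0	-23.0	49.0
58	Postcentral_R	R	43.0	-23.0	49.0
59	Parietal_Sup_L	L	-24.0	-60.0	59.0
60	Parietal_Sup_R	R	24.0	-60.0	59.0
61	Parietal_Inf_L	L	-44.0	-46.0	47.0
62	Parietal_Inf_R	R	44.0	-46.0	47.0
63	SupraMarginal_L	L	-57.0	-32.0	34.0
64	SupraMarginal_R	R	57.0	-32.0	34.0
65	Angular_L	L	-45.0	-61.0	36.0
66	Angular_R	R	45.0	-61.0	36.0
67	Precuneus_L	L	-8.0	-56.0	48.0
68	Precuneus_R	R	8.0	-56.0	48.0
69	Paracentral_Lobule_L	L	-6.0	-25.0	70.0
70	Paracentral_Lobule_R	R	6.0	-25.0	70.0
71	Caudate_L	L	-12.0	11.0	9.0
72	Caudate_R	R	12.0	11.0	9.0
73	Putamen_L	L	-25.0	4.0	2.0
74	Putamen_R	R	25.0	4.0	2.0
75	Pallidum_L	L	-20.0	0.0	0.0
76	Pallidum_R	R	20.0	0.0	0.0
77	Thalamus_L	L	-12.0	-18.0	8.0
78	Thalamus_R	R	12.0	-18.0	8.0
79	Heschl_L	L	-43.0	-19.0	10.0
80	Heschl_R	R	43.0	-19.0	10.0
81	Temporal_Sup_L	L	-54.0	-21.0	7.0
82	Temporal_Sup_R	R	54.0	-21.0	7.0
83	Temporal_Pole_Sup_L	L	-41.0	15.0	-20.0
84	Temporal_Pole_Sup_R	R	41.0	15.0	-20.0
85	Temporal_Mid_L	L	-56.0	-34.0	-2.0
86	Temporal_Mid_R	R	56.0	-34.0	-2.0
87	Temporal_Pole_Mid_L	L	-39.0	15.0	-32.0
88	Temporal_Pole_Mid_R	R	39.0	15.0	-32.0
89	Temporal_Inf_L	L	-51.0	-47.0	-20.0
90	Temporal_Inf_R	R	51.0	-47.0	-20.0
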