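id	age	sex	ll_pre_ml	ll_post_ml	edss_pre	edss_post	symptoms
MS01	28	f	1.72	1.30	3.0	1.0	Internuclear ophthalmoplegia
MS02	23	f	3.93	6.06	2.0	n.a.	Facial nerve paralysis
MS03	54	f	19.13	21.61	3.0	1.5	Paresis left leg, restricted walking range, limb ataxia
MS04	21	f	0.36	0.36	2.0	1.5	Optic neuritis
MS05	23	f	14.41	13.42	2.0	1.0	Optic neuritis, facial nerve paralysis, mild fatigue, sensory disturbances
MS06	27	f	n.a.	1.53	3.0	n.a.	Optic neuritis, sensory disturbances
MS07	29	m	0.85	0.69	2.5	1.0	Gait ataxia, sensory disturbances
MS08	22	f	0.02	0.14	1.0	1.0	Optic neuritis
MS09	22	f	1.41	0.41	2.0	0.0	Optic neuritis
MS10	21	f	1.93	1.62	3.0	2.0	Optic neuritis
MS11	24	f	8.97	3.30	3.0	n.a.	Tetraparesis, gait ataxia
MS12	35	m	0.44	0.46	2.5	n.a.	Cerebellar ataxia
MS13	33	f	4.58	4.81	2.0	n.a.	Slight ataxia, paresis of the left leg
MS14	18	m	1.28	0.94	1.0	1.0	Vertigo, gait ataxia
MS15	23	f	0.03	0.02	2.0	1.0	Optic neuritis
MS16	35	m	0.45	1.41	2.5	3.0	Sensory disturbances, fatigue
MS17	26	f	1.67	1.62	2.0	n.a.	Optic neuritis
MS18	46	f	0.19	0.16	4.0	1.0	Optic neuritis
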