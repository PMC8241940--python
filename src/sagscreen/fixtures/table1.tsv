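genome_id	kind	cag	completeness	checkm_contamination	corrected_contamination	tier	size_mb	predicted_size_mb	gc	taxonomy	evidence	novelty
CAG1	CAG		68.8	0	0	mq	0.72	1.05	44.7	Cand. Saccharibacteria	sgm	Novel species
S2_E04	SAG	CAG1	35.9	0	0	lq	0.36	1	44
S3_L12	SAG	CAG1	47	0	0	lq	0.47	0.99	46.7
S5_F09	SAG		10.3	0	0	lq	0.25	2.39	45.8	Cand. Saccharibacteria	sm	n. d.
CAG2	CAG		89.7	1.9	0.9	mq	1.33	1.5	32.1	Cand. Komeilibacteria	sgm	Same novel family as CAG3 but different genus
S1_H12	SAG	CAG2	65.5	0.2	0.2	mq	0.77	1.17	31.5
S5_K02	SAG	CAG2	61.9	0	0	mq	0.91	1.48	31.7
S5_K13	SAG	CAG2	82.7	0	0	mq	1.06	1.28	31.5
CAG3	CAG		70.7	13	7.8	mq	1.34	2.13	33.3	Cand. Komeilibacteria	sgm	Same novel family as CAG2 but different genus
S1_I04	SAG	CAG3	38.1	1.7	1.7	lq	0.63	1.72	32.8
S2_K09	SAG	CAG3	55.7	4.7	4.7	mq	0.81	1.59	34
S3_J02	SAG	CAG3	23.8	2.2	0.8	lq	0.55	2.37	30.9
S3_E16	SAG		12.1	4.3	0	lq	0.33	2.74	30.5	Cand. Komeilibacteria	sm	n. d.
CAG4	CAG		82.8	12.1	9.4	mq	2.17	2.96	44.4	Cand. Falkowbacteria	sgm	Novel genus
S1_L12	SAG	CAG4	52.1	1.2	1.2	mq	0.63	1.23	40
S2_E10	SAG	CAG4	40.5	4.7	3.5	lq	1.25	3.37	48.1
S2_J07	SAG	CAG4	20.4	0.9	0	lq	0.34	1.66	41.5
S3_K08	SAG	CAG4	50	1.7	1.7	mq	0.83	1.72	38
S3_L10	SAG	CAG4	44.1	7.8	2.6	lq	0.42	1.02	38.8
S4_F15	SAG	CAG4	36.7	0	0.9	lq	0.5	1.41	39.1
S5_F19	SAG	CAG4	44	0	0	lq	0.61	1.39	37.7
S5_I03	SAG	CAG4	71.2	2.6	1.3	mq	1.11	1.59	38.6
S1_J13	SAG		36.1	0	0	lq	0.42	1.18	35.1	Cand. Shapirobacteria	sgm	Novel species
S1_L17	SAG		29.8	0	0	lq	0.5	1.68	36.1	Cand. Shapirobacteria	sgm	Novel genus
S1_L14	SAG		39.9	1.7	1.7	lq	0.65	1.7	30.9	Cand. Shapirobacteria	sgm	Novel species, same genus as S2_F12, S3_E17, S4_G10
S2_F12	SAG		66.6	0	0	mq	0.86	1.3	34.7	Cand. Shapirobacteria	sgm	Novel species, same genus as S1_L14, S3_E17, S4_G10
S3_E17	SAG		23	0	0	lq	0.69	3	32.3	Cand. Shapirobacteria	gm	Novel species, same genus as S1_L14, S2_F12, S4_G10
S4_G10	SAG		23.4	0	0	lq	0.55	2.35	38.7	Cand. Shapirobacteria	sgm	Novel species, same genus as S1_L14, S2_F12, S3_E17
S4_G22	SAG		33	0	0	lq	0.74	2.25	36.7	Cand. Roizmanbacteria	sgm	Novel species
S2_J21	SAG		50.7	0	0	mq	0.63	1.25	36.2	Cand. Dojkabacteria	sg	Novel genus
S5_H10	SAG		62.3	0	0	mq	0.95	1.53	36.2	Cand. Gracilibacteria	sgm	Novel family
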