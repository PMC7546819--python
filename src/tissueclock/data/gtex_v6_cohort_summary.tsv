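Tissue	Number	Minimum	Maximum	Median	Mean	NumMen	NumWomen	Proportion
Adipose_subcutaneous	350	21	70	55	52	219	131	1.672
Adipose_visceral_(omentum)	227	21	70	54	52	145	82	1.768
Adrenal_gland	145	21	70	51	51	81	64	1.266
Artery_aorta	224	21	69	54	51	138	86	1.605
Artery_coronary	133	21	69	54	52	77	56	1.375
Artery_tibial	332	20	70	53	51	213	119	1.79
Brain_amygdala	72	20	70	60	58	50	22	2.273
Brain_anterior_cingulate_cortex_(BA24)	84	20	70	60	58	61	23	2.652
Brain_caudate_(basal_ganglia)	117	20	70	60	58	85	32	2.656
Brain_cerebellar_hemisphere	105	20	70	59	56	74	31	2.387
Brain_cerebellum	125	20	70	59	57	84	41	2.049
Brain_cortex	114	20	70	59	57	77	37	2.081
Brain_frontal_cortex_(BA9)	108	23	70	60	58	77	31	2.484
Brain_hippocampus	94	20	70	60	57	65	29	2.241
Brain_hypothalamus	96	20	70	60	58	71	25	2.84
Brain_nucleus_accumbens_(basal_ganglia)	113	20	70	60	57	79	34	2.324
Brain_putamen_(basal_ganglia)	97	20	70	59	57	69	28	2.464
Brain_spinal_cord_(cervical_c-1)	71	22	70	59	57	43	28	1.536
Breast_mammary_tissue	214	21	70	53	51	124	90	1.378
Cells_EBV-transformed_lymphocytes	118	21	70	50	48	75	43	1.744
Cells_transformed_fibroblasts	284	21	70	53.5	51	181	103	1.757
Colon_sigmoid	149	21	70	56	54	88	61	1.443
Colon_transverse	196	21	70	50	48	115	81	1.42
Esophagus_gastroesophageal_junction	153	21	70	53	51	94	59	1.593
Esophagus_mucosa	286	21	70	52.5	50	179	107	1.673
Esophagus_muscularis	247	21	70	50	49	157	90	1.744
Heart_atrial_appendage	194	20	70	55	54	126	68	1.853
Heart_left_ventricle	218	20	70	53	51	142	76	1.868
Liver	119	21	69	55	54	78	41	1.902
Lung	320	21	70	54	52	213	107	1.991
Muscle_skeletal	430	20	70	54.5	52	274	156	1.756
nerve_tibial	304	20	70	54	52	199	105	1.895
Ovary	97	21	69	51	50	97	NA	NA
Pancreas	171	21	70	51	50	102	69	1.478
Pituitary	103	20	70	59	57	74	29	2.552
Prostate	106	21	70	50.5	49	106	NA	NA
Skin_not_sun_exposed_(suprapubic)	250	20	70	55	53	164	86	1.907
Skin_sun_exposed_(lower_leg)	357	21	70	55	52	226	131	1.725
Small_intestine_terminal_ileum	88	21	70	49.5	48	51	37	1.378
Spleen	104	21	68	50	48	60	44	1.364
Stomach	193	21	70	51	48	111	82	1.354
Testis	172	21	70	52	50	172	NA	NA
Thyroid	323	20	70	55	53	211	112	1.884
Uterus	83	21	69	50	48	83	NA	NA
Vagina	96	21	69	51	50	96	NA	NA
Whole_blood	393	20	70	54	52	249	144	1.729
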