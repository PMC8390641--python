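tissue	median_cterm_fraction	mean_cterm_fraction	n_samples
Spleen	0.042	0.0539	118
Skin-Not Sun Exposed (Suprapubic)	0.041	0.0579	271
Skin-Sun Exposed (Lower leg)	0.041	0.0509	397
Small Intestine-Terminal Ileum	0.035	0.0699	104
Whole Blood	0.034	0.0651	449
Fallopian Tube	0.031	0.0276	7
Breast-Mammary Tissue	0.029	0.0373	218
Bladder	0.029	0.0444	10
Cervix-Ectocervix	0.028	0.0367	6
Lung	0.024	0.0453	372
Minor Salivary Gland	0.023	0.0340	70
Adipose-Subcutaneous	0.022	0.0345	385
Cells-EBV-transformed lymphocytes	0.014	0.0154	138
Colon-Transverse	0.013	0.0214	202
Stomach	0.011	0.0287	203
Esophagus-Mucosa	0.010	0.0162	330
Thyroid	0.000	0.0260	359
Testis	0.000	0.0205	202
Ovary	0.000	0.0123	108
Vagina	0.000	0.0174	97
Heart-Atrial Appendage	0.000	0.0185	216
Brain-Caudate (basal ganglia)	0.000	0.0027	133
Esophagus-Muscularis	0.000	0.0184	282
Brain-Putamen (basal ganglia)	0.000	0.0002	101
Brain-Anterior cingulate cortex (BA24)	0.000	0.0058	95
Adrenal Gland	0.000	0.0132	159
Brain-Cerebellum	0.000	0.0044	128
Cervix-Endocervix	0.000	0.0120	5
Brain-Cerebellar Hemisphere	0.000	0.0071	93
Artery-Coronary	0.000	0.0226	140
Liver	0.000	0.0174	135
Esophagus-Gastroesophageal Junction	0.000	0.0136	176
Brain-Hippocampus	0.000	0.0011	99
Brain-Hypothalamus	0.000	0.0049	97
Prostate	0.000	0.0186	118
Brain-Amygdala	0.000	0.0019	78
Pancreas	0.000	0.0271	196
Heart-Left Ventricle	0.000	0.0163	266
Brain-Cortex	0.000	0.0027	130
Muscle-Skeletal	0.000	0.0180	468
Brain-Spinal cord (cervical c-1)	0.000	0.0085	70
Uterus	0.000	0.0110	90
Brain-Nucleus accumbens (basal ganglia)	0.000	0.0037	121
Pituitary	0.000	0.0061	124
Artery-Aorta	0.000	0.0224	246
Kidney-Cortex	0.000	0.0169	36
Brain-Frontal Cortex (BA9)	0.000	0.0055	116
Adipose-Visceral (Omentum)	0.000	0.0286	234
Cells-Transformed fibroblasts	0.000	0.0059	305
Artery-Tibial	0.000	0.0212	362
Colon-Sigmoid	0.000	0.0164	173
Nerve-Tibial	0.000	0.0178	334
Brain-Substantia nigra	0.000	0.0063	69
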