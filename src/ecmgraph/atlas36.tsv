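abbrev	name	network	x	y	z
PCC	Posterior cingulate/Precuneus	DMN	0	-52	27
MPFC	Medial Prefrontal cortex	DMN	-1	54	27
lIPL	Left lateral parietal lobe	DMN	-46	-66	30
rIPL	Right lateral parietal lobe	DMN	49	-63	33
lITG	Left inferior temporal gyrus	DMN	-61	-24	-9
rITG	Right inferior temporal gyrus	DMN	58	-24	-9
MDT	Medial dorsal thalamus	DMN	0	-12	9
lPCer	Left posterior cerebellum	DMN	-25	-81	-33
rPCer	Right posterior cerebellum	DMN	25	-81	-33
lFEF	Left frontal eye field	DAN	-29	-9	54
rFEF	Right frontal eye field	DAN	29	-9	54
lPIPS	Left posterior intraparietal sulcus	DAN	-26	-66	48
rPIPS	Right posterior intraparietal sulcus	DAN	26	-66	48
lAIPS	Left anterior intraparietal sulcus	DAN	-44	-39	45
rAIPS	Right anterior intraparietal sulcus	DAN	41	-39	45
lMTG	Left middle temporal gyrus	DAN	-50	-66	-6
rMTG	Right middle temporal gyrus	DAN	53	-63	-6
DMPFC	Dorsal medial prefrontal cortex	CEN	0	24	46
lAPFC	Left anterior prefrontal cortex	CEN	-44	45	0
rAPFC	Right anterior prefrontal cortex	CEN	44	45	0
lSPG	Left superior parietal gyrus	CEN	-50	-51	45
rSPG	Right superior parietal gyrus	CEN	50	-51	45
DACC	Dorsal anterior cingulate cortex	SN	0	21	36
lAPFC2	Left anterior prefrontal cortex	SN	-35	45	30
rAPFC2	Right anterior prefrontal cortex	SN	32	45	30
lIC	Left insula cortex	SN	-41	3	6
rIC	Right insula cortex	SN	41	3	6
lLPC	Left lateral parietal cortex	SN	-62	-45	30
rLPC	Right lateral parietal cortex	SN	62	-45	30
lM1	Left motor cortex	SMN	-39	-26	51
rM1	Right motor cortex	SMN	38	-26	48
SMA	Supplementary motor area	SMN	0	-21	48
lV1	Left primary visual cortex	VN	-7	-83	2
rV1	Right primary visual cortex	VN	7	-83	2
lA1	Left primary auditory area	AN	-62	-30	12
rA1	Right primary auditory area	AN	59	-27	15
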