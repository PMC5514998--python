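tissue	germ_layer	turnover_days
Adipose tissue	mesoderm	2448
Adrenal gland	ectoderm	455
Bone marrow	mesoderm	3.2
(CD14+) monocytes	mesoderm	2
Colon	endoderm	3.5
Endometrium	mesoderm	13
Esophagus	endoderm	10
Heart muscle	mesoderm	25300
Keratinocytes (skin epidermis)	ectoderm	64
Kidney	mesoderm	270
Liver	endoderm	327
Lung	endoderm	200
Neuron (neocortex)	ectoderm	32850
Osteoblasts (bone)	mesoderm	8.3
Rectum	endoderm	3.5
Salivary gland	ectoderm	60
Skeletal muscle	mesoderm	5510
Smooth muscle	mesoderm	67.5
Spleen	mesoderm	7.8
Thyroid gland	endoderm	3180
Urinary bladder	endoderm	49
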