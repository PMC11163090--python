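class_name	drug_name	is_reference
GLP-1 RA	exenatide	1
GLP-1 RA	Byetta	0
GLP-1 RA	Bydureon	0
GLP-1 RA	liraglutide	0
GLP-1 RA	Victoza	0
GLP-1 RA	Saxenda	0
GLP-1 RA	dulaglutide	0
GLP-1 RA	Trulicity	0
GLP-1 RA	semaglutide	0
GLP-1 RA	Ozempic	0
GLP-1 RA	Rybelsus	0
GLP-1 RA	Wegovy	0
GLP-1 RA	albiglutide	0
GLP-1 RA	Tanzeum	0
GLP-1 RA	lixisenatide	0
GLP-1 RA	Adlyxin	0
DPP-4 inhibitor	sitagliptin	0
DPP-4 inhibitor	Januvia	0
DPP-4 inhibitor	saxagliptin	0
DPP-4 inhibitor	Onglyza	0
DPP-4 inhibitor	linagliptin	0
DPP-4 inhibitor	Tradjenta	0
DPP-4 inhibitor	alogliptin	0
DPP-4 inhibitor	Nesina	0
DPP-4 inhibitor	vildagliptin	0
DPP-4 inhibitor	Galvus	0
SGLT2 inhibitor	empagliflozin	0
SGLT2 inhibitor	Jardiance	0
SGLT2 inhibitor	canagliflozin	0
SGLT2 inhibitor	Invokana	0
SGLT2 inhibitor	dapagliflozin	0
SGLT2 inhibitor	Farxiga	0
SGLT2 inhibitor	ertugliflozin	0
SGLT2 inhibitor	Steglatro	0
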