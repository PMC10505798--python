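name	motif	cut_offset
EcoR I	GAATTC	1
EcoR II	CCWGG	0
Hha I	GCGC	3
Pst I	CTGCAG	5
Dra I	TTTAAA	3
Hinf I	GANTC	1
Hae III	GGCC	2
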