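gene_id	definition_name	atg_pos	allele	source_note
SKC1/OsHKT8	SKC1_elite	+418	ALT	HapK; Nona Bokra allele
SKC1/OsHKT8	SKC1_elite	+551	ALT	HapK; Nona Bokra allele
SKC1/OsHKT8	SKC1_elite	+994	ALT	HapK; Nona Bokra allele
SKC1/OsHKT8	SKC1_elite	+1183	ALT	HapK; Nona Bokra allele
GS3	GS3_elite	+1637	ALT	HapG; premature stop, Minghui63 allele
qSE3/OsHAK21	OsHAK21_elite	+6	REF	HapA & HapB; Jiucaiqing allele
qSE3/OsHAK21	OsHAK21_elite	+807	REF	HapA & HapB; Jiucaiqing allele
qSE3/OsHAK21	OsHAK21_elite	+3740	REF	HapA & HapB; Jiucaiqing allele
qSE3/OsHAK21	OsHAK21_elite	+3870	REF	HapA & HapB; Jiucaiqing allele
qSE3/OsHAK21	OsHAK21_elite	+3889	REF	HapA & HapB; Jiucaiqing allele
qSE3/OsHAK21	OsHAK21_elite	+4082	REF	HapA & HapB; Jiucaiqing allele
qSTG4/OsPAO3	OsPAO3_elite	+3395	ALT	HapB; Teqing allele
qSTG4/OsPAO3	OsPAO3_elite	+3474	ALT	HapB; Teqing allele
qSTG4/OsPAO3	OsPAO3_elite	+3724	ALT	HapB; Teqing allele
RST1/OsARF18	RST1_elite	+1743	REF	HapA & HapB; RST1-HapIII allele
RST1/OsARF18	RST1_elite	+1830	REF	HapA & HapB; RST1-HapIII allele
RST1/OsARF18	RST1_elite	+1986	REF	HapA & HapB; RST1-HapIII allele
RST1/OsARF18	RST1_elite	+2102	REF	HapA & HapB; RST1-HapIII allele
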