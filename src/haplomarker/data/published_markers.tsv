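gene	variation_position	variation_id	marker_type	marker_name	primer_f	primer_r	reference_size	restriction_enzyme	haplotypes
SKC1/OsHKT8	-1250	vg0111464525	dCAPS	SKC1 5Ud	ACTGAGCATCTCAGATGATC	ACCGGCTAGAGTGGTGAATT	194/(20, 174)	EcoR I	HapK-2/3/4/5
SKC1/OsHKT8	+551	vg0111462725	CAPS	SKC1 E1C	ACTCCTCCAAGATGATAGCA	GAGACGACGGTGAAGATG	423/(202, 221)	Hha I	HapK-1/2/3/4/5
SKC1/OsHKT8	+1964	vg0111461312	dCAPS	SKC1 I1d	ACATGGATTGACGCTTcCAG	ATAACCTTCATCTAGCTAG	(20, 175)/195	EcoR II	HapK-1/2/3/4
GS3	+1637	vg0316733441	CAPS	GS3 E2C	AAAGTTGACAGGCTAAACAC	GCTTGCACGATACTATGATT	427/(130, 297)	Pst I	HapG-1/2/3
qSE3/OsHAK21	-2447		Indel	HAK21 5U2	TGACAGAGTGAGTGGCTAT	GCTGACTGGAATACTATGTAGA	(+391)/262		HapF-2 & HapJ
qSE3/OsHAK21	-1169	vg0321066133	Indel	HAK21 5U1	AGGGTTTCACTTCTACTT	ACACTCGTACATCCACAAG	(-17)/179		HapF-2 & HapJ
qSE3/OsHAK21	+1251	vg0321063718	CAPS	HAK21 I2C	GGTGACGGTTAGTGTTCTC	TCTTCCGCCTGATGGTTA	(172, 300)/472	Dra I	HapA & HapB
qSTG4/OsPAO3	+3474	vg0431670265	dCAPS	PAO3 E9d	CTCGACTCCAACTGAGAaTT	CCACCATTCCTTATTGCTAATC	210/(20, 190)	EcoR I	HapB
RST1/OsARF18	-2858		Indel	ARF18 5U	GGTGACGAGAGATCGGAC	CTGTATGCAAATTGGGAC	866/(-514)		HapA & HapB
RST1/OsARF18	-1505	vg0628585614	CAPS	ARF18 5UC	TTATATGGCATTAGGCAATCC	TATACTCGCATGTGAAGGTT	195/(36, 159)	Hinf I	HapA & HapB
RST1/OsARF18	+1612	vg0628588730	CAPS	ARF18 E2C	GGTTGGTCCTATGTGCTATT	GTGCCATTCTGATTACTTCTC	(126, 315)/441	Hae III	HapA & HapB
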