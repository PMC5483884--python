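# Curated shortlist of radiation-quality-exclusive Arabidopsis biomarker candidates.
# multiplicity = number of plant species contributing at least one orthologue
# annotated to the category (pre-computed against the 39-species snapshot).
category	gene	multiplicity
gamma-ray	RAD54	30
gamma-ray	AT4G14970	30
gamma-ray	RPA1A	27
gamma-ray	MSH5	23
gamma-ray	RAD51	18
X-ray	ATLIG4	28
X-ray	MIM	7
X-ray	SMC6A	6
UV-A	AT2G21970.1	2
UV-B	UVH3	32
UV-B	RPA70B	7
UV-B	RPA70D	5
UV-B	XPB1	4
UV-B	XPB2	4
UV-B	AT3G48900	1
UV-C	TED4	3
UV-C	MC4	2
UV-C	MC7	2
UV-C	MC5	2
UV-C	MC6	2
UV-C	MC8	2
UV-C	HO4	1
UV-C	HO3	1
UV-C	ETL1	1
UV-C	PCC1	1
UV-C	PAD4	1
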