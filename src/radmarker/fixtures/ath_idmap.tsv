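# Arabidopsis gene -> RefSeq protein accession for the shortlisted candidates.
gene_id	protein_id
RAD54	NP_188552
AT4G14970	NP_193233
RPA1A	NP_973433
MSH5	NP_188683
RAD51	NP_172254
ATLIG4	NP_568851
MIM	NP_200954
SMC6A	NP_196383
SEP2	NP_565524
UVH3	NP_566830
RPA70B	NP_196419
RPA70D	NP_200908
XPB2	NP_568591
XPB1	NP_568592
GEN2	NP_001118795
TED4	NP_001118392
MC4	NP_178052
MC8	NP_173092
MC7	NP_178049
MC5	NP_178051
MC6	NP_178050
HO4	NP_176126
HO3	NP_177130
ETL1	NP_178318
PCC1	NP_566702
PAD4	NP_190811
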