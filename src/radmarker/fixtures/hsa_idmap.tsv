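# Human HGNC symbol -> Ensembl protein identifier (MSH5 has seven isoform entries).
gene_id	protein_id
RAD54B	ENSP00000336606
RAD54L	ENSP00000396113
FANCD2	ENSP00000287647
RPA1	ENSP00000254719
MSH5	ENSP00000364894
MSH5	ENSP00000387668
MSH5	ENSP00000394619
MSH5	ENSP00000394649
MSH5	ENSP00000406868
MSH5	ENSP00000407047
MSH5	ENSP00000409207
RAD51D	ENSP00000378090
LIG4	ENSP00000402030
SMC6	ENSP00000370672
ERCC5	ENSP00000347978
ERCC3	ENSP00000285398
SMARCAD1	ENSP00000351947
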