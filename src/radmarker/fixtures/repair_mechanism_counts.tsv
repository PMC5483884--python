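# Printed per-mechanism gene counts from the cross-kingdom DNA-repair comparison
# (2016 database snapshot; counts are fixture inputs, percentages are recomputed).
# n_hs / n_at: annotated genes; orth_hs / orth_at: of those, genes with >=1
# orthologue in the other species; new_hs / new_at: genes suggested in new roles.
mechanism	go_term	n_hs	orth_hs	pct_hs	n_at	orth_at	pct_at	new_hs	new_at
DNA repair	GO:0006281	507	259	51.1	300	185	61.7	86	243
BER	GO:0006284	52	32	61.5	29	12	41.4	3	36
NER	GO:0006289	124	59	47.6	30	21	70.0	5	57
MMR	GO:0006298	43	14	32.6	17	12	70.6	0	1
HR	GO:0000724	162	76	46.9	50	37	74.0	38	87
NHEJ	GO:0006303	73	9	12.3	7	4	57.1	0	8
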