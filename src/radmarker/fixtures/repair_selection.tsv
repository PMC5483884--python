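term_id	category
GO:0006281	DNA repair
GO:0006284	BER
GO:0006289	NER
GO:0006298	MMR
GO:0000724	HR
GO:0006303	NHEJ
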