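term_id	category
GO:0010212	Ionizing Radiation
GO:0010165	X-ray
GO:0010332	gamma-ray
GO:0009411	UV
GO:0070141	UV-A
GO:0010224	UV-B
GO:0010225	UV-C
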