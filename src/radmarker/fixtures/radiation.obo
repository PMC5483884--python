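format-version: 1.2
ontology: radmarker/radiation-response-snapshot
remark: Minimal snapshot of the response-to-radiation branch of the Gene Ontology covering the seven curated radiation-quality terms and their stated parentage.

[Term]
id: GO:0009314
name: response to radiation

[Term]
id: GO:0010212
name: response to ionizing radiation
is_a: GO:0009314 ! response to radiation

[Term]
id: GO:0010165
name: response to X-ray
is_a: GO:0010212 ! response to ionizing radiation

[Term]
id: GO:0010332
name: response to gamma radiation
is_a: GO:0010212 ! response to ionizing radiation

[Term]
id: GO:0009416
name: response to light stimulus
is_a: GO:0009314 ! response to radiation

[Term]
id: GO:0009411
name: response to UV
is_a: GO:0009416 ! response to light stimulus

[Term]
id: GO:0070141
name: response to UV-A
is_a: GO:0009411 ! response to UV

[Term]
id: GO:0010224
name: response to UV-B
is_a: GO:0009411 ! response to UV

[Term]
id: GO:0010225
name: response to UV-C
is_a: GO:0009411 ! response to UV

[Typedef]
id: part_of
name: part of
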