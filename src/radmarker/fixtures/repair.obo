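format-version: 1.2
ontology: radmarker/dna-repair-snapshot
remark: Minimal snapshot of the DNA-repair branch of the Gene Ontology covering the six curated repair-pathway terms.

[Term]
id: GO:0006281
name: DNA repair

[Term]
id: GO:0006284
name: base-excision repair
is_a: GO:0006281 ! DNA repair

[Term]
id: GO:0006289
name: nucleotide-excision repair
is_a: GO:0006281 ! DNA repair

[Term]
id: GO:0006298
name: mismatch repair
is_a: GO:0006281 ! DNA repair

[Term]
id: GO:0006302
name: double-strand break repair
is_a: GO:0006281 ! DNA repair

[Term]
id: GO:0000724
name: double-strand break repair via homologous recombination
is_a: GO:0006302 ! double-strand break repair

[Term]
id: GO:0006303
name: double-strand break repair via nonhomologous end joining
is_a: GO:0006302 ! double-strand break repair

[Typedef]
id: part_of
name: part of
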