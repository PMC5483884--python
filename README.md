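# radmarker

Comparative-genomics tooling for two linked analyses in radiation biology:

1. **Plant radiation biodosimeter screening** — selecting *Arabidopsis
   thaliana* genes whose annotation is *exclusive* to one radiation quality
   (X-ray, γ-ray, UV-A, UV-B or UV-C), supported by orthologues across many
   plant species, so their expression can indicate both radiation exposure
   and radiation type in the field.
2. **Cross-kingdom DNA-repair comparison** — pairing human and Arabidopsis
   genes of the five main repair pathways (BER, NER, MMR, HR, NHEJ) through
   orthogroups, and inferring *new* candidate repair genes: genes that share
   an orthogroup with annotated repair genes of the other species without
   having been annotated to that pathway themselves.

Both analyses run entirely on file-based snapshots (OBO ontology files,
annotation TSV/GAF, STRING-style edge lists, OrthoMCL-style group files) and
on seeded synthetic corpora with planted ground truth — no live database
access.

## The method

The screening pipeline chains five stages:

* **Ontology closure.** From a root GO term (e.g. `GO:0009314` *response to
  radiation*), repeatedly collect direct child terms over `is_a`/`part_of`
  edges until a fixed point; validate a curated selection of category terms
  against that closure and report which descendants it leaves uncovered.
* **Orthologue projection.** For each species and category term, map the
  species' annotated genes onto reference-species genes through an
  orthologue map, keeping full provenance. The *multiplicity* of a
  (category, gene) claim is the number of distinct species supporting it.
* **Exclusivity filter.** A full Venn decomposition of the per-category gene
  sets (2^k − 1 cells); genes in more than one *leaf* quality category are
  excluded, genes only under parent terms are reported separately.
* **Network scoring.** On a confidence-thresholded protein–protein
  interaction graph (STRING-style 0–1000 scores, default threshold 400),
  each node's *clique score* counts **all** cliques of ≥ 3 vertices that
  contain it; weighted degree breaks ties. High scorers are the
  "dense-clique node" candidates.
* **Ranking and counterpart lookup.** Candidates are ordered by
  (multiplicity desc, network score desc, gene id), and their human
  counterparts are resolved through protein-level orthogroups.

The comparison pipeline classifies each orthogroup by which of the two taxa
it contains, pairs annotated co-members (counted into per-mechanism coverage
percentages, rounded half-up to one decimal), infers unannotated co-members
as new candidate genes, and optionally expands one hop: each annotated
gene's other groups are scanned once for further unannotated same-taxon
members.

## Worked example

The packaged orthogroup toy has six groups A–F: A–C contain both human
(`hsa`) and Arabidopsis (`ath`) genes, D–E only plant genes, F only human
genes. Annotated inputs are human genes *a, b, d, e* and plant genes
*ii, iii*.

```bash
radmarker fixtures worked-example --out groups.txt
# ann.tsv: hsa a,b,d,e and ath ii,iii annotated under GO:0006281
radmarker repair compare --config cfg.yaml --out out
```

`out/pairs.tsv`:

```text
mechanism	gene_A	gene_B
DNA repair	a	ii
DNA repair	b	iii
DNA repair	d	iii
```

Human gene *a* and plant gene *ii* share group B, so the two characterized
genes are paired as orthologues (likewise *b*/*iii* and *d*/*iii* through
group C). `out/new_genes.tsv`:

```text
mechanism	taxon	gene	hop
DNA repair	hsa	c	0
DNA repair	ath	i	0
DNA repair	ath	iv	1
```

Genes *c* and *i* sit in group A next to annotated gene *a* without being
annotated themselves — they are inferred as new candidate repair genes.
Gene *iv* is found only at expansion depth 1: annotated plant gene *ii* is
used as a second query, reaching the plant-only group D that contains *iv*.
Group F holds only human genes, so its annotated gene *e* is excluded and
appears nowhere. `out/summary.tsv` reports the per-mechanism counts: 3 of
the 4 annotated human genes have an orthologue pair (75.0%), both plant
genes do (100.0%), and one new gene is suggested per taxon.

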