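# Methods

## Scope and model

The package operationalises two file-based comparative analyses:

* a **screen for radiation-quality-exclusive biomarker genes** in a
  reference plant species, aggregated over many species through orthology;
* an **orthogroup-mediated comparison of DNA-repair gene sets** between two
  taxa, including the inference of unannotated ("new") candidate genes.

All database-shaped inputs (ontology, annotations, orthologue maps,
orthogroups, interaction networks, id maps) are snapshots on disk. Results
therefore describe a snapshot, not a live resource; headline counts from any
particular public-database vintage are treated as fixture data, not as
recomputable outputs.

## Ontology stage

The term DAG is read from OBO with typed child→parent edges mapped onto
{`is_a`, `part_of`, `regulates`, `other`}. Closures use the least fixed
point of direct-descendant expansion; the default relation set is
{`is_a`, `part_of`}, matching the ancestry conventions of common GO
browsers. Obsolete terms are kept but flagged, and excluded from closures by
default because they carry no annotations. Term ids are normalised to
`GO:` + 7 digits and `alt_id`s resolve to canonical ids. The `is_a` graph is
checked for cycles at load and a cycle member is named on failure.

Which descendants of a root are "sufficient" as analysis categories is a
curatorial judgement, not an algorithm: the selection is an input, and the
module validates membership and emits a coverage report (descendants of the
root outside every curated term's own closure) rather than second-guessing
the curator.

## Projection and multiplicity

Annotations are per (species, term) gene sets; GAF rows with a `NOT`
qualifier are dropped. Orthology is allowed to be many-to-many: a source
gene with several reference counterparts contributes provenance to each.
The reference species participates through the identity map. Source genes
without a reference counterpart are dropped but tallied, since silent loss
would bias multiplicity. Multiplicity counts **distinct species** in a
record's provenance, not orthologue genes — one species with three
paralogues supports a claim once. Ranking sorts by multiplicity desc, then
network score desc, then gene id ascending; the scientifically meaningful
quantity is the multiplicity, the rest is deterministic tie-breaking.

## Exclusivity filter

The Venn partition is computed exactly over all 2^k − 1 category subsets
(guarded at k ≤ 16); cells are indexed by frozen category subsets, so
k beyond what diagram software draws is unproblematic. Exclusivity is
evaluated on **leaf** quality categories only: a gene annotated to a parent
term (ionizing radiation, UV) in addition to exactly one leaf remains
exclusive; genes with no leaf membership go to a separate parent-only
report instead of being forced into either decision. Gene ids compare by
exact string equality after whitespace trim, preserving case (AGI locus
codes are case-significant by convention).

## Network stage

"Dense-clique node" is operationalised as the count of all cliques of size
≥ `min_clique_size` (default 3) containing a node, on the graph thresholded
at `min_score` (default 400, the STRING "medium confidence" cut). Counting
all cliques rather than only maximal ones makes the score monotone under
edge addition and directly enumerable by an exhaustive-subset oracle on
small graphs. Maximal cliques are enumerated first as a tractability guard
(hard error above 10^5), then distinct cliques are counted per node.
Weighted degree (Σ incident scores / 1000) is the documented tie-breaker.
Scores stay 0–1000 integers at I/O for bit-exact round-trips and are
normalised to [0, 1] internally.

## Orthogroup transfer

Groups are parsed from the `GROUP_ID: taxon|gene ...` text format; members
of taxa outside the pair of interest are legal and inert. Only groups
containing at least one annotated query gene take part, mirroring how
groups are actually retrieved (by querying annotated genes). In a group
with members of both taxa, annotated×annotated co-members become orthologue
pairs and unannotated members of either taxon become new candidates; a
group whose annotated members all belong to one taxon, with no member of
the other, is recorded as excluded. Expansion is **one hop only**
(depth ∈ {0, 1}): each annotated gene's groups are scanned once more for
unannotated same-taxon members. Unbounded transitive closure would
flood-fill entire orthogroup neighbourhoods and is deliberately not
offered.

"New" status is per mechanism: a gene annotated for one pathway can be new
for another. Counterpart lookup operates at protein level (RefSeq /
Ensembl-protein ids) and collapses isoforms back to genes through the id
maps: a gene pair exists if any protein of one co-occurs with any protein
of the other.

Coverage percentages are 100·(genes with orthologues)/(annotated genes),
rounded **half-up** to one decimal — this rule reproduces every printed
percentage in the packaged per-mechanism count table from its count pair.
Two counting rules are exposed because "has an orthologue" is ambiguous:
`pair` (default) counts a gene iff it appears in ≥ 1 orthologue pair;
`group` counts it iff it sits in any group shared with the other taxon.

## Synthetic corpora

Generators are pure functions of (seed, parameters); a corpus-level seed is
fanned out to independent per-generator streams via `numpy` seed sequences,
so reruns are byte-identical.

* **Projection corpus defaults** mirror the study scale: 39 species, the
  7 radiation-quality terms, a 410-gene reference pool. Rates default to
  annotation_rate 0.35, cross_category_overlap 0.10, orthology_retention
  0.90 — values chosen once as realistic for GO-annotation sparsity and
  orthologue-call coverage in plants. With overlap 0, retention 1 and rate
  1 the construction guarantees that the exclusivity output equals the
  planted exclusive sets exactly; recovery tests use that regime.
* **Orthogroup corpus**: groups cycle through both/one-taxon classes;
  exactly `planted_new` unannotated genes are placed into shared groups, so
  depth-0 transfer recovers them with precision = recall = 1 at zero noise.
* **PPI generator**: planted cliques are fully wired at score 999,
  background pairs are Bernoulli(p) at score 500. With 40 nodes and
  background p ≤ 0.05 the planted 5-clique members occupy the top-5 clique
  ranks in ≳ 95% of seeds.

What the synthetic corpora do **not** emulate: phylogenetic correlation
between species (annotations are independent across species), gene-family
birth/death, realistic orthogroup size distributions, annotation biases
toward well-studied genes, and STRING's evidence-channel structure. Passing
recovery tests therefore demonstrates algorithmic correctness under the
stated generative assumptions, not robustness to the biases of real
databases.

## Numerical and procedural choices

* Percentage rounding: decimal half-up at 1 decimal (never banker's
  rounding), via `decimal.Decimal`.
* All output tables are sorted on documented keys, so pipeline reruns are
  byte-identical.
* Degenerate inputs: empty annotation sets yield empty-but-valid outputs;
  empty OBO bodies yield empty DAGs; an empty edge file yields an empty
  network with zero scores.
* Problem sizes in the test and acceptance runs (≤ 50-term DAGs for
  closure oracles, ≤ 15-node graphs for the subset-enumeration clique
  oracle, ≤ 100 genes for the transfer oracle, 100 seeds for the clique
  Monte-Carlo) are chosen as the largest sizes where the independent
  brute-force oracles remain exact and fast.

## Known limitations

* The eligibility rule that reduces a descendant closure to a curated
  selection is not modelled — the selection is an input by design.
* Clique enumeration is exponential in the worst case; the maximal-clique
  cap makes failure explicit rather than slow.
* The one-hop expansion can surface genes whose only link to the mechanism
  is a single annotated co-member; multiplicities and network scores are
  not propagated to expansion hits.
* GAF parsing extracts (taxon, object id, term, qualifier) only; evidence
  codes are not filtered.
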