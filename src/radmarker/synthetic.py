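"""Seeded synthetic corpora with the structure the screening pipeline assumes.

Every generator is a pure function of its seed and parameters, so reruns are
byte-identical and each downstream stage can be tested against planted ground
truth: which genes were placed in exactly one radiation category, which
unannotated genes were planted in shared orthogroups, which nodes carry a
planted dense clique. The default corpus emulates the scale of the published
screen: 39 plant species, seven radiation-quality terms and a reference gene
pool of 410 genes.

A small worked orthogroup example (groups A-F, genes a-e / i-iv) is packaged
as a text fixture and exposed through :func:`worked_example`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np

from .ontology import TermDag, TermRecord, TermSelection
from .projection import OrthologMap, SpeciesAnnotationSet
from .network import PpiNetwork, from_scored_edges
from .transfer import OrthoGroup, load_orthogroups

__all__ = [
    "CorpusSpec",
    "PlantedTruth",
    "default_radiation_selection",
    "gen_go_dag",
    "gen_projection_corpus",
    "gen_orthogroup_corpus",
    "gen_ppi",
    "worked_example",
    "fixture_path",
]

PLANTED_EDGE_SCORE = 999
BACKGROUND_EDGE_SCORE = 500


def fixture_path(name: str):
    """Path to a packaged text fixture (context-manager-free; files are real on disk)."""
    return resources.files("radmarker.fixtures") / name


def default_radiation_selection() -> TermSelection:
    """The seven curated radiation-quality terms as a ready-made selection."""
    selected = (
        ("GO:0010212", "response to ionizing radiation", "Ionizing Radiation"),
        ("GO:0010165", "response to X-ray", "X-ray"),
        ("GO:0010332", "response to gamma radiation", "gamma-ray"),
        ("GO:0009411", "response to UV", "UV"),
        ("GO:0070141", "response to UV-A", "UV-A"),
        ("GO:0010224", "response to UV-B", "UV-B"),
        ("GO:0010225", "response to UV-C", "UV-C"),
    )
    return TermSelection(root_id="GO:0009314", selected=selected)


@dataclass(frozen=True)
class CorpusSpec:
    """Study conditions for a synthetic projection corpus.

    Defaults mirror the published screen's scale (39 species x 7 terms over a
    410-gene reference pool); the rates are desk-realistic: roughly a third of
    (species, gene, category) annotations observed, mild cross-category
    overlap, and 90% of source genes with a called reference orthologue.
    """

    seed: int = 0
    n_species: int = 39
    terms: TermSelection = field(default_factory=default_radiation_selection)
    gene_pool_size: int = 410
    annotation_rate: float = 0.35
    cross_category_overlap: float = 0.10
    orthology_retention: float = 0.90

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if not 0 < self.annotation_rate <= 1:
            raise ValueError("annotation_rate must be in (0, 1]")
        if not 0 <= self.cross_category_overlap <= 1:
            raise ValueError("cross_category_overlap must be in [0, 1]")
        if not 0 < self.orthology_retention <= 1:
            raise ValueError("orthology_retention must be in (0, 1]")


@dataclass
class PlantedTruth:
    planted_exclusive: dict[str, frozenset[str]] = field(default_factory=dict)
    planted_new_genes: frozenset[tuple[str, str, str]] = frozenset()
    planted_clique_nodes: frozenset[str] = frozenset()


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def gen_go_dag(depth: int, branching: int, seed: int = 0) -> TermDag:
    """A rooted random term DAG: ``branching`` children per level-parent slot.

    Level l holds branching**l terms; each attaches by is_a to a random parent
    on level l-1, with an occasional extra part_of edge to a second parent
    (making it a DAG rather than a tree). Every non-root term is reachable
    from the root.
    """
    if depth < 1 or branching < 1:
        raise ValueError("depth and branching must be >= 1")
    rng = np.random.default_rng(seed)
    terms: dict[str, TermRecord] = {}
    edges: set[tuple[str, str, str]] = set()

    def tid(i: int) -> str:
        return f"SYN:{i:07d}"

    counter = 0
    root = tid(counter)
    terms[root] = TermRecord(root, "synthetic root")
    counter += 1
    levels: list[list[str]] = [[root]]
    for level in range(1, depth + 1):
        prev = levels[-1]
        current: list[str] = []
        for parent in prev:
            for _ in range(branching):
                term = tid(counter)
                counter += 1
                terms[term] = TermRecord(term, f"synthetic term level {level}")
                edges.add((term, parent, "is_a"))
                # occasional second parent at the same upper level
                if len(prev) > 1 and rng.random() < 0.2:
                    other = prev[int(rng.integers(len(prev)))]
                    if other != parent:
                        edges.add((term, other, "part_of"))
                current.append(term)
        levels.append(current)
    return TermDag(terms=terms, edges=edges)


def gen_projection_corpus(
    spec: CorpusSpec,
) -> tuple[list[SpeciesAnnotationSet], list[OrthologMap], PlantedTruth]:
    """Annotation sets, orthologue maps and planted truth for one corpus.

    One annotation set exists per (species, term) pair — n_species x n_terms
    sets in total, empty ones included. The first species is the reference
    and annotates its own gene ids (identity projection); every other species
    carries species-local source gene ids whose reference counterpart exists
    with probability ``orthology_retention``. Each reference gene gets one
    primary category, plus one extra with probability
    ``cross_category_overlap``; genes with exactly one category make up
    ``planted_exclusive``.
    """
    rng_cat, rng_ann, rng_orth = _streams(spec.seed, 3)
    categories = list(spec.terms.categories)
    term_of = {cat: tid for tid, _n, cat in spec.terms.selected}
    species = [f"plant_{i + 1:02d}" for i in range(spec.n_species)]
    reference = species[0]
    genes = [f"G{i + 1:05d}" for i in range(spec.gene_pool_size)]

    cats_of: dict[str, tuple[str, ...]] = {}
    for gene in genes:
        primary = categories[int(rng_cat.integers(len(categories)))]
        cats = [primary]
        if len(categories) > 1 and rng_cat.random() < spec.cross_category_overlap:
            extra = primary
            while extra == primary:
                extra = categories[int(rng_cat.integers(len(categories)))]
            cats.append(extra)
        cats_of[gene] = tuple(cats)
    planted_exclusive = {
        cat: frozenset(g for g in genes if cats_of[g] == (cat,)) for cat in categories
    }

    maps: list[OrthologMap] = []
    source_of: dict[tuple[str, str], str] = {}
    for sp in species[1:]:
        pairs: set[tuple[str, str]] = set()
        for i, gene in enumerate(genes):
            src = f"{sp}_g{i + 1:05d}"
            source_of[(sp, gene)] = src
            if rng_orth.random() < spec.orthology_retention:
                pairs.add((src, gene))
        maps.append(OrthologMap(sp, frozenset(pairs)))

    annotations: list[SpeciesAnnotationSet] = []
    for sp in species:
        per_term: dict[str, set[str]] = {term_of[c]: set() for c in categories}
        for gene in genes:
            for cat in cats_of[gene]:
                if rng_ann.random() < spec.annotation_rate:
                    src = gene if sp == reference else source_of[(sp, gene)]
                    per_term[term_of[cat]].add(src)
        for cat in categories:  # keep all (species, term) sets, even empty ones
            annotations.append(
                SpeciesAnnotationSet(sp, term_of[cat], frozenset(per_term[term_of[cat]]))
            )
    truth = PlantedTruth(planted_exclusive=planted_exclusive)
    return annotations, maps, truth


def gen_orthogroup_corpus(
    n_groups: int,
    n_genes_per_taxon: int,
    planted_new: int,
    seed: int = 0,
    taxon_a: str = "hsa",
    taxon_b: str = "ath",
    mechanism: str = "synthetic",
) -> tuple[list[OrthoGroup], frozenset[str], frozenset[str], PlantedTruth]:
    """Orthogroups with annotated members of two taxa and planted new genes.

    Returns (groups, annotated_A, annotated_B, truth). Groups cycle through
    the classes both / A-only / B-only; shared ('both') groups hold annotated
    genes of both taxa, single-taxon groups hold annotated genes only. The
    ``planted_new`` unannotated genes are each placed in exactly one shared
    group, so at zero noise the transfer stage recovers them exactly.
    """
    rng = np.random.default_rng(seed)
    if n_groups < 1 or n_genes_per_taxon < 2:
        raise ValueError("need n_groups >= 1 and n_genes_per_taxon >= 2")
    genes_a = [f"{taxon_a}_g{i + 1:04d}" for i in range(n_genes_per_taxon)]
    genes_b = [f"{taxon_b}_g{i + 1:04d}" for i in range(n_genes_per_taxon)]
    n_ann = max(1, int(round(0.6 * n_genes_per_taxon)))
    annotated_a, spare_a = genes_a[:n_ann], genes_a[n_ann:]
    annotated_b, spare_b = genes_b[:n_ann], genes_b[n_ann:]

    classes = ["both", "A_only", "B_only"]
    groups_members: dict[str, set[tuple[str, str]]] = {}
    shared_ids: list[str] = []
    for i in range(n_groups):
        gid = f"OGS_{i + 1:04d}"
        cls = classes[i % 3]
        members: set[tuple[str, str]] = set()
        if cls in ("both", "A_only"):
            k = int(rng.integers(1, min(3, len(annotated_a)) + 1))
            members.update(
                (taxon_a, annotated_a[j])
                for j in rng.choice(len(annotated_a), size=k, replace=False)
            )
        if cls in ("both", "B_only"):
            k = int(rng.integers(1, min(3, len(annotated_b)) + 1))
            members.update(
                (taxon_b, annotated_b[j])
                for j in rng.choice(len(annotated_b), size=k, replace=False)
            )
        groups_members[gid] = members
        if cls == "both":
            shared_ids.append(gid)

    spare = [(taxon_a, g) for g in spare_a] + [(taxon_b, g) for g in spare_b]
    if planted_new > len(spare) or (planted_new > 0 and not shared_ids):
        raise ValueError(
            f"cannot plant {planted_new} new genes: "
            f"{len(spare)} unannotated genes available, {len(shared_ids)} shared groups"
        )
    order = rng.permutation(len(spare))
    planted: set[tuple[str, str, str]] = set()
    for k in range(planted_new):
        taxon, gene = spare[order[k]]
        gid = shared_ids[int(rng.integers(len(shared_ids)))]
        groups_members[gid].add((taxon, gene))
        planted.add((taxon, gene, mechanism))

    groups = [
        OrthoGroup(gid, frozenset(members))
        for gid, members in sorted(groups_members.items())
        if members
    ]
    truth = PlantedTruth(planted_new_genes=frozenset(planted))
    return groups, frozenset(annotated_a), frozenset(annotated_b), truth


def gen_ppi(
    n_nodes: int,
    background_p: float,
    planted_cliques: Sequence[tuple[int, Sequence[str] | None]] = (),
    seed: int = 0,
) -> tuple[PpiNetwork, PlantedTruth]:
    """A background Bernoulli graph with fully wired planted cliques.

    ``planted_cliques`` is a list of (size, members) with members optional
    (drawn without replacement when None). Planted edges carry the maximum
    confidence score, background edges a mid score; a pair covered by both
    keeps the planted score.
    """
    rng = np.random.default_rng(seed)
    nodes = [f"g{i + 1:03d}" for i in range(n_nodes)]
    node_set = set(nodes)

    planted_nodes: set[str] = set()
    planted_edges: set[frozenset[str]] = set()
    for size, members in planted_cliques:
        if size < 3:
            raise ValueError("planted clique size must be >= 3")
        if members is None:
            idx = rng.choice(n_nodes, size=size, replace=False)
            members = [nodes[i] for i in idx]
        members = list(members)
        if len(members) != size or not set(members) <= node_set:
            raise ValueError("clique members must be `size` distinct known nodes")
        planted_nodes.update(members)
        for i in range(size):
            for j in range(i + 1, size):
                planted_edges.add(frozenset((members[i], members[j])))

    triples: list[tuple[str, str, int]] = []
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            pair = frozenset((nodes[i], nodes[j]))
            if pair in planted_edges:
                triples.append((nodes[i], nodes[j], PLANTED_EDGE_SCORE))
            elif background_p > 0 and rng.random() < background_p:
                triples.append((nodes[i], nodes[j], BACKGROUND_EDGE_SCORE))
    net = from_scored_edges(triples)
    return net, PlantedTruth(planted_clique_nodes=frozenset(planted_nodes))


def worked_example() -> tuple[list[OrthoGroup], frozenset[str], frozenset[str], dict]:
    """The packaged A-F orthogroup toy with its asserted expectations.

    Returns (groups, annotated_hsa, annotated_ath, expected) where
    ``expected`` holds only the relations the toy is defined to guarantee:
    the (a, ii) orthologue pair, new Arabidopsis gene i, new human gene c,
    the second-hop gene iv (reachable only at expansion depth 1), and the
    exclusion of the human-only group F carrying annotated gene e.
    """
    groups = load_orthogroups(fixture_path("worked_example_groups.txt"))
    annotated_hsa = frozenset({"a", "b", "d", "e"})
    annotated_ath = frozenset({"ii", "iii"})
    expected = {
        "pairs": {("a", "ii")},
        "new_A": {"c"},
        "new_B": {"i"},
        "expansion_new": {("ath", "iv")},
        "excluded_groups": {"F"},
    }
    return groups, annotated_hsa, annotated_ath, expected
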