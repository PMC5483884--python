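"""Shared fixtures and independent oracles used across the suite.

The oracle helpers deliberately avoid the library code paths they check:
reachability by boolean-matrix fixed point, Venn cells by per-gene membership
bitmask, clique scores by exhaustive vertex-subset enumeration, and transfer
by a literal triple scan over (annotated gene, group, member).
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest

from radmarker.ontology import TermDag, TermRecord
from radmarker.synthetic import fixture_path


@pytest.fixture(scope="session")
def radiation_dag():
    from radmarker.ontology import load_obo

    return load_obo(fixture_path("radiation.obo"))


@pytest.fixture(scope="session")
def repair_dag():
    from radmarker.ontology import load_obo

    return load_obo(fixture_path("repair.obo"))


def random_dag(n_terms: int, edge_p: float, seed: int) -> TermDag:
    """Random DAG built straight from dataclasses (bypasses gen_go_dag):
    edges only from later to earlier index, so acyclicity is structural."""
    rng = np.random.default_rng(seed)
    ids = [f"T:{i:03d}" for i in range(n_terms)]
    terms = {t: TermRecord(t) for t in ids}
    edges = set()
    for j in range(1, n_terms):
        parents = [i for i in range(j) if rng.random() < edge_p]
        if not parents:
            parents = [int(rng.integers(j))]
        for i in parents:
            rel = "is_a" if rng.random() < 0.8 else "part_of"
            edges.add((ids[j], ids[i], rel))
    return TermDag(terms=terms, edges=edges)


def reachability_oracle(dag: TermDag, root: str, relations) -> frozenset[str]:
    """Transitive closure of the child relation by repeated boolean matmul."""
    ids = sorted(dag.terms)
    idx = {t: i for i, t in enumerate(ids)}
    n = len(ids)
    adj = np.zeros((n, n), dtype=bool)  # adj[p, c]: c is a direct child of p
    for child, parent, rel in dag.edges:
        if rel in relations:
            adj[idx[parent], idx[child]] = True
    closure = adj.copy()
    while True:
        nxt = closure | (closure @ adj)
        if (nxt == closure).all():
            break
        closure = nxt
    return frozenset(ids[c] for c in np.flatnonzero(closure[idx[root]]))


def venn_oracle(family: dict[str, set[str]]) -> dict[frozenset, set[str]]:
    """Per-gene membership bitmask classification."""
    cats = list(family)
    cells: dict[frozenset, set[str]] = {
        frozenset(c): set()
        for k in range(1, len(cats) + 1)
        for c in combinations(cats, k)
    }
    universe = set().union(*family.values())
    for gene in universe:
        membership = frozenset(c for c in cats if gene in family[c])
        cells[membership].add(gene)
    return cells


def clique_score_oracle(graph, min_size: int) -> dict[str, int]:
    """Count cliques per node by enumerating every vertex subset of size >= min_size."""
    nodes = sorted(graph.nodes)
    counts = {n: 0 for n in nodes}
    for k in range(min_size, len(nodes) + 1):
        for subset in combinations(nodes, k):
            if all(graph.has_edge(u, v) for u, v in combinations(subset, 2)):
                for n in subset:
                    counts[n] += 1
    return counts


def transfer_oracle(annotated_a, annotated_b, groups, taxon_a, taxon_b):
    """Exhaustive triple scan over (annotated gene, group, member)."""
    pairs, new_a, new_b, excluded = set(), set(), set(), set()
    ann_a, ann_b = set(annotated_a), set(annotated_b)
    for group in groups:
        reached = False
        for taxon, gene in group.members:
            if (taxon == taxon_a and gene in ann_a) or (
                taxon == taxon_b and gene in ann_b
            ):
                reached = True
        if not reached:
            continue
        has_a = any(t == taxon_a for t, _ in group.members)
        has_b = any(t == taxon_b for t, _ in group.members)
        if has_a and has_b:
            for ta, ga in group.members:
                for tb, gb in group.members:
                    if ta == taxon_a and tb == taxon_b:
                        if ga in ann_a and gb in ann_b:
                            pairs.add((ga, gb))
            for taxon, gene in group.members:
                if taxon == taxon_a and gene not in ann_a:
                    new_a.add(gene)
                if taxon == taxon_b and gene not in ann_b:
                    new_b.add(gene)
        else:
            excluded.add(group.group_id)
    return pairs, new_a, new_b, excluded
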