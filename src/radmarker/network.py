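"""Clique-participation scoring on confidence-weighted interaction networks.

"Dense-clique node" candidates are operationalised as the genes that sit in
many cliques of a score-thresholded protein-protein interaction graph: the
clique score of a node is the number of *all* cliques (not only maximal ones)
of at least ``min_size`` vertices that contain it. Weighted degree (sum of
incident confidence scores on the 0-1 scale) breaks ties. Edge scores follow
the STRING convention of integers in [0, 1000] at I/O.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "PpiNetwork",
    "load_edges",
    "clique_node_scores",
    "select_hub_candidates",
    "write_edges_tsv",
]

MAX_MAXIMAL_CLIQUES = 100_000


@dataclass
class PpiNetwork:
    """Undirected simple graph; edge attribute ``weight`` holds score/1000."""

    graph: nx.Graph

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_score(self, a: str, b: str) -> int:
        """Raw 0-1000 integer score of an edge."""
        return round(self.graph.edges[a, b]["weight"] * 1000)


def from_scored_edges(edges: Iterable[tuple[str, str, int]], min_score: int = 0) -> PpiNetwork:
    """Build a network from (a, b, score-in-[0,1000]) triples.

    Self-loops are dropped; duplicate undirected edges collapse keeping the
    maximum score; edges below ``min_score`` are then filtered out.
    """
    best: dict[frozenset[str], int] = {}
    for a, b, score in edges:
        if a == b:
            continue
        if not 0 <= score <= 1000:
            raise ValueError(f"score {score} outside [0, 1000] for edge ({a}, {b})")
        key = frozenset((a, b))
        best[key] = max(best.get(key, 0), int(score))
    g = nx.Graph()
    for key, score in best.items():
        if score >= min_score:
            a, b = sorted(key)
            g.add_edge(a, b, weight=score / 1000)
    return PpiNetwork(g)


def load_edges(path, min_score: int = 400) -> PpiNetwork:
    """Read a STRING-style edge TSV (node_a, node_b, combined_score).

    A header row is recognised by a non-numeric third column. Sub-threshold
    edges are dropped; duplicates collapse keeping the max score.
    """
    triples: list[tuple[str, str, int]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            a, b, raw = parts[0].strip(), parts[1].strip(), parts[2].strip()
            try:
                score = int(raw)
            except ValueError:
                if lineno == 1:  # header
                    continue
                raise ValueError(f"{path}:{lineno}: non-numeric score {raw!r}") from None
            triples.append((a, b, score))
    return from_scored_edges(triples, min_score=min_score)


def clique_node_scores(net: PpiNetwork, min_size: int = 3) -> pd.DataFrame:
    """Per-node count of all cliques of size >= min_size, plus weighted degree.

    Enumeration goes through maximal cliques first as a tractability guard
    (error above MAX_MAXIMAL_CLIQUES), then counts distinct cliques of every
    qualifying size. Rows sorted by (clique_score desc, weighted_degree desc,
    node asc).
    """
    if min_size < 3:
        raise ValueError("min_size must be >= 3")
    g = net.graph

    n_maximal = 0
    for _ in nx.find_cliques(g):
        n_maximal += 1
        if n_maximal > MAX_MAXIMAL_CLIQUES:
            raise RuntimeError(
                f"graph has more than {MAX_MAXIMAL_CLIQUES} maximal cliques"
            )

    counts: dict[str, int] = {node: 0 for node in g.nodes}
    for clique in nx.enumerate_all_cliques(g):
        if len(clique) < min_size:
            continue
        for node in clique:
            counts[node] += 1

    wdeg = {
        node: sum(d["weight"] for _u, _v, d in g.edges(node, data=True))
        for node in g.nodes
    }
    df = pd.DataFrame(
        {
            "node": list(counts),
            "clique_score": [counts[n] for n in counts],
            "weighted_degree": [wdeg[n] for n in counts],
        }
    )
    return df.sort_values(
        ["clique_score", "weighted_degree", "node"],
        ascending=[False, False, True],
        ignore_index=True,
    )


def select_hub_candidates(
    scores: pd.DataFrame,
    pool: Mapping[str, Iterable[str]],
    top_n: int,
) -> dict[str, list[str]]:
    """Per category, the pool members ranked by clique participation.

    Sort key: (clique_score desc, weighted_degree desc, gene asc); genes
    absent from the network score 0. The list is truncated to ``top_n``.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    table = {
        row.node: (int(row.clique_score), float(row.weighted_degree))
        for row in scores.itertuples()
    }
    out: dict[str, list[str]] = {}
    for category, genes in pool.items():
        ranked = sorted(
            set(genes),
            key=lambda gene: (
                -table.get(gene, (0, 0.0))[0],
                -table.get(gene, (0, 0.0))[1],
                gene,
            ),
        )
        out[category] = ranked[:top_n]
    return out


def write_edges_tsv(net: PpiNetwork, path) -> None:
    """Bit-exact STRING-style output: integer scores on the 0-1000 scale."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("node_a\tnode_b\tcombined_score\n")
        for a, b in sorted(tuple(sorted(e)) for e in net.graph.edges):
            fh.write(f"{a}\t{b}\t{net.edge_score(a, b)}\n")
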