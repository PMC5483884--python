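"""Venn partitioning of category -> gene-set families and exclusivity filtering.

The screening step that keeps only radiation-quality-*exclusive* genes: a full
2^k - 1 cell decomposition of k gene sets (cells indexed by frozen category
subsets, so k can exceed what diagram software draws), followed by extraction
of the genes that belong to exactly one of the designated leaf categories.
Genes annotated only under parent categories (e.g. "response to UV" but none
of UV-A/B/C) are reported separately rather than silently discarded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

__all__ = ["VennPartition", "ExclusiveResult", "partition", "exclusive_genes"]

_MAX_CATEGORIES = 16  # 2^16 cells is already far past any curated selection


@dataclass(frozen=True)
class VennPartition:
    categories: tuple[str, ...]
    cells: Mapping[frozenset[str], frozenset[str]]
    universe: frozenset[str]

    def cell(self, *categories: str) -> frozenset[str]:
        return self.cells[frozenset(categories)]

    def sizes(self) -> dict[str, int]:
        """Cell sizes keyed by '&'-joined sorted category labels."""
        return {
            "&".join(sorted(subset)): len(genes)
            for subset, genes in sorted(
                self.cells.items(), key=lambda kv: sorted(kv[0])
            )
        }

    def to_json(self) -> str:
        return json.dumps(self.sizes(), indent=2, sort_keys=True)


@dataclass(frozen=True)
class ExclusiveResult:
    exclusive: Mapping[str, frozenset[str]]
    parent_only: frozenset[str]


def _as_family(family) -> list[tuple[str, frozenset[str]]]:
    if isinstance(family, Mapping):
        items = list(family.items())
    else:
        items = list(family)
    names = [name for name, _ in items]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise ValueError(f"duplicate category names: {sorted(dupes)}")
    return [(name, frozenset(str(g).strip() for g in genes)) for name, genes in items]


def partition(family) -> VennPartition:
    """Full Venn decomposition of a category -> gene-set family.

    Every non-empty category subset S gets a cell: the genes in all sets of S
    and in none outside S. Empty cells are retained. Gene ids are compared by
    exact string equality after whitespace trim.
    """
    items = _as_family(family)
    if not items:
        raise ValueError("at least one category is required")
    if len(items) > _MAX_CATEGORIES:
        raise ValueError(f"more than {_MAX_CATEGORIES} categories")

    categories = tuple(name for name, _ in items)
    sets = dict(items)
    universe = frozenset().union(*sets.values()) if sets else frozenset()

    cells: dict[frozenset[str], frozenset[str]] = {}
    for k in range(1, len(categories) + 1):
        for combo in combinations(categories, k):
            inside = frozenset(combo)
            cell = frozenset.intersection(*(sets[c] for c in combo))
            for other in categories:
                if other not in inside:
                    cell -= sets[other]
            cells[inside] = cell
    return VennPartition(categories=categories, cells=cells, universe=universe)


def exclusive_genes(part: VennPartition, leaf_categories: Sequence[str]) -> ExclusiveResult:
    """Genes belonging to exactly one leaf category.

    Membership in non-leaf (parent) categories does not disqualify a gene:
    the exclusivity test looks only at the leaf coordinates of each cell.
    Genes in no leaf category at all come back as ``parent_only``.
    """
    leaves = list(leaf_categories)
    unknown = [c for c in leaves if c not in part.categories]
    if unknown:
        raise KeyError(f"unknown categories: {unknown}")
    leaf_set = frozenset(leaves)

    exclusive: dict[str, set[str]] = {c: set() for c in leaves}
    parent_only: set[str] = set()
    for subset, genes in part.cells.items():
        leaf_members = subset & leaf_set
        if len(leaf_members) == 1:
            (leaf,) = leaf_members
            exclusive[leaf].update(genes)
        elif not leaf_members:
            parent_only.update(genes)
        # genes in >=2 leaf categories are excluded entirely
    return ExclusiveResult(
        exclusive={c: frozenset(s) for c, s in exclusive.items()},
        parent_only=frozenset(parent_only),
    )
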