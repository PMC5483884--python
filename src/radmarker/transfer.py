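"""Orthogroup-based comparison of annotated gene sets between two taxa.

Given per-mechanism annotated gene sets for two species (here human and
Arabidopsis) and a table of orthogroups (clusters of orthologous genes across
many taxa), this module:

* classifies each group by which of the two taxa of interest it contains;
* pairs already-annotated genes of the two taxa that share a group;
* infers *new* candidate genes — unannotated genes sitting in a shared group
  next to annotated ones, hence suggested for the same mechanism;
* optionally expands one hop: every annotated gene's other groups are scanned
  once and their unannotated same-taxon members collected;
* records groups that contain annotated genes of one taxon but no member of
  the other as excluded (they can support no cross-taxon claim);
* summarises per-mechanism counts and orthologue-coverage percentages.

"New" status is per mechanism: a gene annotated for one repair pathway can
still be new for another.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "OrthoGroup",
    "IdMap",
    "TransferResult",
    "load_orthogroups",
    "write_orthogroups",
    "load_idmap",
    "classify_groups",
    "transfer",
    "find_counterpart_orthologs",
    "summarize",
    "round_pct",
]


@dataclass(frozen=True)
class OrthoGroup:
    group_id: str
    members: frozenset[tuple[str, str]]  # (taxon, gene_id)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"group {self.group_id} has no members")

    def genes_of(self, taxon: str) -> frozenset[str]:
        return frozenset(g for t, g in self.members if t == taxon)

    def has_taxon(self, taxon: str) -> bool:
        return any(t == taxon for t, _g in self.members)


@dataclass(frozen=True)
class IdMap:
    """gene <-> protein mapping for one taxon; a gene may have several proteins."""

    taxon: str
    entries: frozenset[tuple[str, str]]  # (gene_id, protein_id)

    def proteins_of(self, gene: str) -> frozenset[str]:
        return frozenset(p for g, p in self.entries if g == gene)

    def genes_of(self, protein: str) -> frozenset[str]:
        return frozenset(g for g, p in self.entries if p == protein)


@dataclass
class TransferResult:
    mechanism: str = ""
    pairs: set[tuple[str, str]] = field(default_factory=set)
    new_A: set[str] = field(default_factory=set)
    new_B: set[str] = field(default_factory=set)
    excluded_groups: set[str] = field(default_factory=set)
    expansion_new: set[tuple[str, str]] = field(default_factory=set)
    #: annotated genes of each taxon that sit in >=1 group also containing the
    #: other taxon (the "group" orthologue-coverage counting rule).
    in_shared_group_A: set[str] = field(default_factory=set)
    in_shared_group_B: set[str] = field(default_factory=set)


def load_orthogroups(path) -> list[OrthoGroup]:
    """Parse an OrthoMCL-style groups file: ``GROUP_ID: taxon|gene taxon|gene ...``.

    Taxa outside any particular pair of interest are legal members and kept.
    '#' comment lines and blank lines are skipped.
    """
    groups: list[OrthoGroup] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            head, sep, rest = line.partition(":")
            if not sep or not head.strip():
                raise ValueError(f"{path}:{lineno}: missing 'GROUP_ID:' prefix")
            group_id = head.strip()
            if group_id in seen:
                raise ValueError(f"{path}:{lineno}: duplicate group id {group_id!r}")
            seen.add(group_id)
            members: set[tuple[str, str]] = set()
            for token in rest.split():
                taxon, sep2, gene = token.partition("|")
                if not sep2 or not taxon or not gene:
                    raise ValueError(
                        f"{path}:{lineno}: malformed member {token!r} (expected taxon|gene)"
                    )
                members.add((taxon, gene))
            if not members:
                raise ValueError(f"{path}:{lineno}: group {group_id!r} has no members")
            groups.append(OrthoGroup(group_id, frozenset(members)))
    return groups


def write_orthogroups(groups: Iterable[OrthoGroup], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for group in sorted(groups, key=lambda g: g.group_id):
            members = " ".join(f"{t}|{g}" for t, g in sorted(group.members))
            fh.write(f"{group.group_id}: {members}\n")


def load_idmap(path, taxon: str) -> IdMap:
    """Read a 2-column (gene_id, protein_id) TSV; '#' lines and a header skipped."""
    entries: set[tuple[str, str]] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
            if parts[0].strip().lower() in ("gene_id", "gene"):
                continue
            entries.add((parts[0].strip(), parts[1].strip()))
    return IdMap(taxon, frozenset(entries))


def classify_groups(
    groups: Iterable[OrthoGroup], taxon_A: str, taxon_B: str
) -> dict[str, str]:
    """Each group -> 'both' | 'A_only' | 'B_only' | 'neither' by taxon presence."""
    if taxon_A == taxon_B:
        raise ValueError("taxa must be distinct")
    out: dict[str, str] = {}
    for group in groups:
        has_a, has_b = group.has_taxon(taxon_A), group.has_taxon(taxon_B)
        if has_a and has_b:
            out[group.group_id] = "both"
        elif has_a:
            out[group.group_id] = "A_only"
        elif has_b:
            out[group.group_id] = "B_only"
        else:
            out[group.group_id] = "neither"
    return out


def transfer(
    annotated_A: Iterable[str],
    annotated_B: Iterable[str],
    groups: Iterable[OrthoGroup],
    taxon_A: str,
    taxon_B: str,
    expansion_depth: int = 0,
    mechanism: str = "",
) -> TransferResult:
    """Pair annotated orthologues and infer new candidate genes through groups.

    Only groups containing at least one annotated gene take part (groups are
    reached by querying annotated genes). In a group holding members of both
    taxa, annotated A x annotated B co-members become pairs and unannotated
    members of either taxon become new_A / new_B. A group whose annotated
    genes all belong to one taxon and which has no member of the other taxon
    is excluded. At ``expansion_depth=1`` every annotated gene's groups are
    scanned once more and unannotated genes of the *same* taxon found there
    are collected into ``expansion_new`` (the second-hop query step).
    """
    if expansion_depth not in (0, 1):
        raise ValueError("expansion_depth must be 0 or 1")
    ann_a, ann_b = frozenset(annotated_A), frozenset(annotated_B)
    result = TransferResult(mechanism=mechanism)

    for group in groups:
        genes_a, genes_b = group.genes_of(taxon_A), group.genes_of(taxon_B)
        hit_a, hit_b = genes_a & ann_a, genes_b & ann_b
        if not hit_a and not hit_b:
            continue  # group never reached by an annotated query
        if genes_a and genes_b:
            result.pairs.update((a, b) for a in sorted(hit_a) for b in sorted(hit_b))
            result.new_A.update(genes_a - ann_a)
            result.new_B.update(genes_b - ann_b)
            result.in_shared_group_A.update(hit_a)
            result.in_shared_group_B.update(hit_b)
        else:
            # annotated genes of one taxon only, no member of the other taxon
            result.excluded_groups.add(group.group_id)
        if expansion_depth == 1:
            if hit_a:
                result.expansion_new.update(
                    (taxon_A, g) for g in genes_a - ann_a
                )
            if hit_b:
                result.expansion_new.update(
                    (taxon_B, g) for g in genes_b - ann_b
                )
    return result


def find_counterpart_orthologs(
    query_genes: Iterable[str],
    groups: Iterable[OrthoGroup],
    query_idmap: IdMap,
    target_idmap: IdMap,
    target_taxon: str,
) -> pd.DataFrame:
    """Per query gene: its protein(s), the orthogroup(s) holding them, and the
    target-taxon proteins/genes found there.

    Groups are protein-level here (isoforms collapse back to genes through the
    target id map). Genes whose proteins belong to no group get group 'none';
    genes missing from the query id map are flagged 'unresolved'.
    """
    groups = list(groups)
    by_protein: dict[tuple[str, str], list[OrthoGroup]] = {}
    for group in groups:
        for member in group.members:
            by_protein.setdefault(member, []).append(group)

    rows = []
    for gene in sorted(set(query_genes)):
        proteins = sorted(query_idmap.proteins_of(gene))
        if not proteins:
            rows.append(
                {
                    "query_gene": gene,
                    "query_protein": "",
                    "group_id": "none",
                    "target_proteins": "",
                    "target_genes": "",
                    "status": "unresolved",
                }
            )
            continue
        hit_groups: list[OrthoGroup] = []
        for protein in proteins:
            hit_groups.extend(by_protein.get((query_idmap.taxon, protein), []))
        if not hit_groups:
            rows.append(
                {
                    "query_gene": gene,
                    "query_protein": ";".join(proteins),
                    "group_id": "none",
                    "target_proteins": "",
                    "target_genes": "",
                    "status": "no_group",
                }
            )
            continue
        group_ids = sorted({g.group_id for g in hit_groups})
        target_proteins: set[str] = set()
        for group in hit_groups:
            target_proteins.update(group.genes_of(target_taxon))
        target_genes: set[str] = set()
        for protein in target_proteins:
            target_genes.update(target_idmap.genes_of(protein))
        rows.append(
            {
                "query_gene": gene,
                "query_protein": ";".join(proteins),
                "group_id": ";".join(group_ids),
                "target_proteins": ";".join(sorted(target_proteins)),
                "target_genes": ";".join(sorted(target_genes)),
                "status": "ok",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "query_gene",
            "query_protein",
            "group_id",
            "target_proteins",
            "target_genes",
            "status",
        ],
    )


def round_pct(numerator: int, denominator: int) -> float:
    """100 * numerator / denominator, rounded half-up to one decimal."""
    if denominator == 0:
        return 0.0
    pct = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def summarize(
    results: Sequence[TransferResult],
    annotated_sizes: Mapping[str, tuple[int, int]],
    orth_count_rule: str = "pair",
) -> pd.DataFrame:
    """Per-mechanism counts and orthologue-coverage percentages.

    ``annotated_sizes`` maps mechanism -> (n_A, n_B). A gene "has an
    orthologue" either when it appears in >=1 orthologue pair (rule 'pair',
    default) or when it sits in any group shared with the other taxon
    (rule 'group').
    """
    if orth_count_rule not in ("pair", "group"):
        raise ValueError("orth_count_rule must be 'pair' or 'group'")
    rows = []
    for res in results:
        n_a, n_b = annotated_sizes[res.mechanism]
        if orth_count_rule == "pair":
            with_a = len({a for a, _b in res.pairs})
            with_b = len({b for _a, b in res.pairs})
        else:
            with_a = len(res.in_shared_group_A)
            with_b = len(res.in_shared_group_B)
        if with_a > n_a or with_b > n_b:
            raise ValueError(
                f"mechanism {res.mechanism!r}: genes with orthologues exceed the "
                f"annotated total ({with_a}/{n_a}, {with_b}/{n_b}); inconsistent inputs"
            )
        rows.append(
            {
                "mechanism": res.mechanism,
                "n_A": n_a,
                "n_A_with_orth": with_a,
                "pct_A": round_pct(with_a, n_a),
                "n_B": n_b,
                "n_B_with_orth": with_b,
                "pct_B": round_pct(with_b, n_b),
                "n_new_A": len(res.new_A),
                "n_new_B": len(res.new_B),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "mechanism",
            "n_A",
            "n_A_with_orth",
            "pct_A",
            "n_B",
            "n_B_with_orth",
            "pct_B",
            "n_new_A",
            "n_new_B",
        ],
    )
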