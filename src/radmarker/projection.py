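"""Orthologue projection of per-species annotation sets onto a reference species.

Each plant species contributes, per GO category, a set of its own genes; an
orthologue map carries those source genes onto reference-species (Arabidopsis)
gene ids. The projected record keeps full provenance — which (species, source
gene) pairs voted for a reference gene — so that *multiplicity*, the number of
distinct species supporting a (category, gene) claim, can be computed and used
to rank biomarker candidates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .ontology import TermSelection, normalize_term_id

__all__ = [
    "SpeciesAnnotationSet",
    "OrthologMap",
    "ProjectedAnnotation",
    "ProjectionReport",
    "load_annotations",
    "project_to_reference",
    "multiplicity",
    "rank_candidates",
    "write_annotations_tsv",
    "write_ortholog_maps_tsv",
    "load_ortholog_maps",
]


@dataclass(frozen=True)
class SpeciesAnnotationSet:
    species: str
    term_id: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.species:
            raise ValueError("species must be non-empty")


@dataclass(frozen=True)
class OrthologMap:
    """source gene (this species) -> reference gene pairs; many-to-many allowed."""

    species: str
    pairs: frozenset[tuple[str, str]]

    def targets(self, source_gene: str) -> frozenset[str]:
        return frozenset(r for s, r in self.pairs if s == source_gene)


@dataclass
class ProjectedAnnotation:
    category: str
    reference_gene: str
    provenance: set[tuple[str, str]] = field(default_factory=set)

    @property
    def multiplicity(self) -> int:
        """Distinct supporting species (not orthologue gene count)."""
        return len({sp for sp, _g in self.provenance})


@dataclass
class ProjectionReport:
    dropped_unmapped: int = 0
    skipped_terms: int = 0


def _is_header(parts: Sequence[str]) -> bool:
    return parts[0].strip().lower() in ("species", "taxon")


def load_annotations(path, dialect: str = "tsv") -> list[SpeciesAnnotationSet]:
    """Read per-species annotations from a 3-column TSV or a GAF 2.x file.

    TSV dialect: columns (species, term_id, gene_id), optional header.
    GAF dialect: species from the taxon column, gene from DB Object ID;
    rows whose qualifier contains ``NOT`` are dropped.
    """
    if dialect not in ("tsv", "gaf"):
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    triples: set[tuple[str, str, str]] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("!") or line.startswith("#"):
                continue
            parts = line.split("\t")
            if dialect == "tsv":
                if len(parts) < 3:
                    raise ValueError(f"{path}:{lineno}: expected 3 tab-separated columns")
                if lineno == 1 and _is_header(parts):
                    continue
                species, term, gene = (p.strip() for p in parts[:3])
            else:  # gaf
                if len(parts) < 13:
                    raise ValueError(f"{path}:{lineno}: GAF row has fewer than 13 columns")
                qualifier = parts[3]
                if "NOT" in qualifier.split("|"):
                    continue
                species = parts[12].split("|")[0].strip()
                term = parts[4].strip()
                gene = parts[1].strip()
            if not species or not term or not gene:
                raise ValueError(f"{path}:{lineno}: empty field")
            triples.add((species, normalize_term_id(term), gene))

    grouped: dict[tuple[str, str], set[str]] = {}
    for species, term, gene in triples:
        grouped.setdefault((species, term), set()).add(gene)
    return [
        SpeciesAnnotationSet(sp, term, frozenset(genes))
        for (sp, term), genes in sorted(grouped.items())
    ]


def load_ortholog_maps(path) -> list[OrthologMap]:
    """Read orthologue maps from a TSV with columns (species, source_gene, reference_gene)."""
    pairs: dict[str, set[tuple[str, str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tab-separated columns")
            if lineno == 1 and _is_header(parts):
                continue
            sp, src, ref = (p.strip() for p in parts[:3])
            pairs.setdefault(sp, set()).add((src, ref))
    return [OrthologMap(sp, frozenset(p)) for sp, p in sorted(pairs.items())]


def project_to_reference(
    sets: Iterable[SpeciesAnnotationSet],
    maps: Iterable[OrthologMap],
    reference: str,
    selection: TermSelection,
) -> tuple[list[ProjectedAnnotation], ProjectionReport]:
    """Carry every species' annotations onto reference-species genes.

    The reference species contributes through the identity map. Source genes
    with no reference counterpart are dropped but tallied in the report, as
    are annotations to terms outside the selection. Output is sorted by
    (category, reference_gene) for determinism.
    """
    sets = list(sets)
    map_by_species = {m.species: m for m in maps}
    species_present = {s.species for s in sets}
    missing = sorted(species_present - set(map_by_species) - {reference})
    if missing:
        raise ValueError(
            "species with annotations but no orthologue map: " + ", ".join(missing)
        )

    # per-species source -> reference lookup, built once
    lookup: dict[str, dict[str, set[str]]] = {}
    for m in map_by_species.values():
        table: dict[str, set[str]] = {}
        for src, ref in m.pairs:
            table.setdefault(src, set()).add(ref)
        lookup[m.species] = table

    report = ProjectionReport()
    acc: dict[tuple[str, str], ProjectedAnnotation] = {}
    for aset in sets:
        category = selection.category_of(normalize_term_id(aset.term_id))
        if category is None:
            report.skipped_terms += 1
            continue
        table = lookup.get(aset.species, {})
        for gene in aset.genes:
            if aset.species == reference:
                refs: set[str] = {gene}
            else:
                refs = table.get(gene, set())
                if not refs:
                    report.dropped_unmapped += 1
                    continue
            for ref_gene in refs:
                key = (category, ref_gene)
                if key not in acc:
                    acc[key] = ProjectedAnnotation(category, ref_gene)
                acc[key].provenance.add((aset.species, gene))
    return [acc[k] for k in sorted(acc)], report


def multiplicity(projected: Iterable[ProjectedAnnotation]) -> pd.DataFrame:
    """Table (category, gene, multiplicity); multiplicity counts distinct species."""
    rows = [
        {"category": p.category, "gene": p.reference_gene, "multiplicity": p.multiplicity}
        for p in projected
    ]
    df = pd.DataFrame(rows, columns=["category", "gene", "multiplicity"])
    return df.sort_values(["category", "gene"], ignore_index=True)


def rank_candidates(
    projected: Iterable[ProjectedAnnotation],
    node_scores: Mapping[str, float],
    shortlist: Iterable[str],
) -> pd.DataFrame:
    """Rank shortlisted genes by (multiplicity desc, node_score desc, gene asc).

    Shortlist genes absent from the projection are warned about and emitted
    with multiplicity 0 at the bottom of the table.
    """
    shortlist = set(shortlist)
    by_gene: dict[str, list[ProjectedAnnotation]] = {}
    for p in projected:
        by_gene.setdefault(p.reference_gene, []).append(p)

    rows = []
    for gene in shortlist:
        score = float(node_scores.get(gene, 0.0))
        if gene in by_gene:
            for p in by_gene[gene]:
                rows.append(
                    {
                        "category": p.category,
                        "gene": gene,
                        "multiplicity": p.multiplicity,
                        "node_score": score,
                    }
                )
        else:
            warnings.warn(f"shortlist gene {gene!r} absent from projection", stacklevel=2)
            rows.append(
                {"category": "", "gene": gene, "multiplicity": 0, "node_score": score}
            )
    df = pd.DataFrame(rows, columns=["category", "gene", "multiplicity", "node_score"])
    df = df.sort_values(
        ["multiplicity", "node_score", "gene"],
        ascending=[False, False, True],
        ignore_index=True,
    )
    return df


def write_annotations_tsv(sets: Iterable[SpeciesAnnotationSet], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("species\tterm_id\tgene_id\n")
        for aset in sorted(sets, key=lambda s: (s.species, s.term_id)):
            for gene in sorted(aset.genes):
                fh.write(f"{aset.species}\t{aset.term_id}\t{gene}\n")


def write_ortholog_maps_tsv(maps: Iterable[OrthologMap], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("species\tsource_gene\treference_gene\n")
        for omap in sorted(maps, key=lambda m: m.species):
            for src, ref in sorted(omap.pairs):
                fh.write(f"{omap.species}\t{src}\t{ref}\n")
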