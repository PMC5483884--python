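"""Ontology snapshots: loading, descendant closures and curated term selections.

A term DAG is read from an OBO flat file (the snapshot of a Gene Ontology
branch) and queried for iterative child-term closures — the procedure of
repeatedly collecting direct descendants of a root term until no new terms
appear. The curated subset of those descendants that the analysis actually
uses (e.g. the five radiation-quality terms, or the five repair pathways)
is a *selection*: this module validates it against the DAG and reports which
descendants of the root the selection leaves uncovered.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import obonet

__all__ = [
    "TermDag",
    "TermSelection",
    "DEFAULT_RELATIONS",
    "load_obo",
    "descendants",
    "select_terms",
    "load_selection_tsv",
    "write_obo",
]

#: Relations treated as "child-of" when computing closures; matches the
#: ancestry conventions of common GO browsers.
DEFAULT_RELATIONS: frozenset[str] = frozenset({"is_a", "part_of"})

_KNOWN_RELATIONS = frozenset({"is_a", "part_of", "regulates"})
_GO_ID_RE = re.compile(r"^(GO):0*(\d+)$", re.IGNORECASE)


def normalize_term_id(term_id: str) -> str:
    """Normalise GO identifiers to upper-case ``GO:`` with 7 digits.

    Non-GO identifiers (synthetic term namespaces) are returned stripped
    but otherwise untouched.
    """
    tid = term_id.strip()
    m = _GO_ID_RE.match(tid)
    if m:
        return f"GO:{int(m.group(2)):07d}"
    return tid


def _normalize_relation(relation: str) -> str:
    rel = relation.strip().lower()
    if rel in ("positively_regulates", "negatively_regulates"):
        rel = "regulates"
    return rel if rel in _KNOWN_RELATIONS else "other"


@dataclass(frozen=True)
class TermRecord:
    term_id: str
    name: str = ""
    obsolete: bool = False


@dataclass
class TermDag:
    """An ontology branch as a DAG of typed child -> parent edges."""

    terms: dict[str, TermRecord] = field(default_factory=dict)
    edges: set[tuple[str, str, str]] = field(default_factory=set)
    alt_ids: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for child, parent, _rel in self.edges:
            if child not in self.terms or parent not in self.terms:
                raise ValueError(
                    f"edge ({child} -> {parent}) references a term absent from the DAG"
                )

    def resolve(self, term_id: str) -> str:
        """Canonical term id: normalised and with alt_ids mapped through."""
        tid = normalize_term_id(term_id)
        return self.alt_ids.get(tid, tid)

    def __contains__(self, term_id: str) -> bool:
        return self.resolve(term_id) in self.terms

    def children_index(self, relations: Iterable[str] = DEFAULT_RELATIONS) -> dict[str, set[str]]:
        """Map parent -> direct children over the given relations."""
        wanted = frozenset(relations)
        index: dict[str, set[str]] = {}
        for child, parent, rel in self.edges:
            if rel in wanted:
                index.setdefault(parent, set()).add(child)
        return index

    def validate_acyclic(self, relations: Iterable[str] = ("is_a",)) -> None:
        wanted = frozenset(relations)
        g = nx.DiGraph(
            (c, p) for c, p, rel in self.edges if rel in wanted
        )
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            return
        member = cycle[0][0]
        raise ValueError(
            f"ontology contains a {'/'.join(sorted(wanted))} cycle through term {member}"
        )


@dataclass(frozen=True)
class TermSelection:
    """A curated, category-tagged subset of descendants of a root term.

    ``uncovered`` is the sufficiency report: descendants of the root that no
    curated term's own closure (term + its descendants) reaches.
    """

    root_id: str
    selected: tuple[tuple[str, str, str], ...]  # (term_id, label, category)
    uncovered: frozenset[str] = frozenset()

    @property
    def term_ids(self) -> tuple[str, ...]:
        return tuple(t for t, _, _ in self.selected)

    @property
    def categories(self) -> tuple[str, ...]:
        return tuple(c for _, _, c in self.selected)

    def category_of(self, term_id: str) -> str | None:
        for tid, _label, cat in self.selected:
            if tid == term_id:
                return cat
        return None

    def __len__(self) -> int:
        return len(self.selected)


def load_obo(path) -> TermDag:
    """Read an OBO 1.2/1.4 flat file into a :class:`TermDag`.

    Obsolete terms are kept but flagged; relationship typedefs are mapped to
    {is_a, part_of, regulates, other}; alt_ids resolve to canonical ids.
    Raises ``ValueError`` if the is_a graph is cyclic.
    """
    graph = obonet.read_obo(str(path), ignore_obsolete=False)

    terms: dict[str, TermRecord] = {}
    alt_ids: dict[str, str] = {}
    for node, data in graph.nodes(data=True):
        tid = normalize_term_id(node)
        obsolete = str(data.get("is_obsolete", "false")).lower() == "true"
        terms[tid] = TermRecord(tid, data.get("name", ""), obsolete)
        for alt in data.get("alt_id", []):
            alt_ids[normalize_term_id(alt)] = tid

    edges: set[tuple[str, str, str]] = set()
    for child, parent, key in graph.edges(keys=True):
        edges.add((normalize_term_id(child), normalize_term_id(parent), _normalize_relation(key)))

    dag = TermDag(terms=terms, edges=edges, alt_ids=alt_ids)
    dag.validate_acyclic(("is_a",))
    return dag


def descendants(
    dag: TermDag,
    root: str,
    relations: Iterable[str] = DEFAULT_RELATIONS,
    include_obsolete: bool = False,
) -> frozenset[str]:
    """All terms reachable from ``root`` by repeated direct-descendant expansion.

    The least fixed point of the "collect direct children, then their
    children, ..." iteration over the given relations. The root itself is
    excluded; obsolete terms are excluded (and not traversed) by default.
    """
    rid = dag.resolve(root)
    if rid not in dag.terms:
        raise KeyError(f"unknown root term {root!r}")
    index = dag.children_index(relations)
    seen: set[str] = set()
    frontier = [rid]
    while frontier:
        nxt: list[str] = []
        for parent in frontier:
            for child in index.get(parent, ()):
                if child in seen:
                    continue
                if not include_obsolete and dag.terms[child].obsolete:
                    continue
                seen.add(child)
                nxt.append(child)
        frontier = nxt
    return frozenset(seen)


def select_terms(
    dag: TermDag,
    root: str,
    curated: Sequence[tuple[str, str]],
    relations: Iterable[str] = DEFAULT_RELATIONS,
) -> TermSelection:
    """Validate a curated (term_id, category) list against the DAG.

    Every curated term must be the root itself or one of its descendants;
    categories must be unique. Which descendants are "sufficient" is a
    curatorial judgement, so this function only validates membership and
    reports coverage: ``uncovered`` lists descendants of the root outside
    every curated term's own descendant closure.
    """
    if not curated:
        raise ValueError("curated selection is empty")
    rid = dag.resolve(root)
    if rid not in dag.terms:
        raise KeyError(f"unknown root term {root!r}")

    root_desc = descendants(dag, rid, relations)
    offenders = []
    resolved: list[tuple[str, str, str]] = []
    seen_cats: set[str] = set()
    for term_id, category in curated:
        tid = dag.resolve(term_id)
        if tid not in dag.terms:
            offenders.append(f"{term_id} (not in ontology)")
            continue
        if tid != rid and tid not in root_desc:
            offenders.append(f"{term_id} (not a descendant of {rid})")
            continue
        if category in seen_cats:
            raise ValueError(f"duplicate category tag {category!r} in selection")
        seen_cats.add(category)
        resolved.append((tid, dag.terms[tid].name, category))
    if offenders:
        raise ValueError("invalid curated terms: " + ", ".join(offenders))

    covered: set[str] = set()
    for tid, _name, _cat in resolved:
        covered.add(tid)
        covered.update(descendants(dag, tid, relations))
    uncovered = frozenset(root_desc - covered)
    return TermSelection(root_id=rid, selected=tuple(resolved), uncovered=uncovered)


def load_selection_tsv(path) -> list[tuple[str, str]]:
    """Read a 2-column (term_id, category) TSV; '#' lines and a header are skipped."""
    rows: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
            if lineno == 1 and parts[0].lower() in ("term_id", "term"):
                continue
            rows.append((parts[0].strip(), parts[1].strip()))
    return rows


def write_obo(dag: TermDag, path) -> None:
    """Write a TermDag back out as a minimal OBO 1.2 file (lossless round-trip)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("format-version: 1.2\n")
        by_child: dict[str, list[tuple[str, str]]] = {}
        for child, parent, rel in sorted(dag.edges):
            by_child.setdefault(child, []).append((parent, rel))
        for tid in sorted(dag.terms):
            rec = dag.terms[tid]
            fh.write(f"\n[Term]\nid: {tid}\n")
            if rec.name:
                fh.write(f"name: {rec.name}\n")
            if rec.obsolete:
                fh.write("is_obsolete: true\n")
            for parent, rel in by_child.get(tid, ()):
                if rel == "is_a":
                    fh.write(f"is_a: {parent}\n")
                else:
                    fh.write(f"relationship: {rel} {parent}\n")
        rels = {rel for _c, _p, rel in dag.edges if rel != "is_a"}
        for rel in sorted(rels):
            fh.write(f"\n[Typedef]\nid: {rel}\nname: {rel}\n")
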