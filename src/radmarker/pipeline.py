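"""End-to-end orchestration of the two analyses, driven by a config mapping.

``run_biodosimeter`` chains ontology -> projection -> exclusivity -> network
scoring -> ranking (-> optional human-counterpart lookup) and writes
per-stage TSVs plus a JSON run manifest. ``run_repair_comparison`` chains
ontology -> per-taxon annotation loading -> per-mechanism orthogroup transfer
-> summary. All outputs are sorted on documented keys so reruns are
byte-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from .network import clique_node_scores, load_edges, select_hub_candidates
from .ontology import load_obo, load_selection_tsv, select_terms
from .projection import (
    load_annotations,
    load_ortholog_maps,
    multiplicity,
    project_to_reference,
    rank_candidates,
)
from .setops import exclusive_genes, partition
from .transfer import (
    find_counterpart_orthologs,
    load_idmap,
    load_orthogroups,
    summarize,
    transfer as run_transfer,
)

__all__ = ["ConfigError", "run_biodosimeter", "run_repair_comparison"]

log = logging.getLogger("radmarker")


class ConfigError(ValueError):
    """A missing or invalid pipeline configuration entry."""


def _require(config: Mapping[str, Any], key: str):
    if key not in config:
        raise ConfigError(f"missing config key {key!r}")
    return config[key]


def _require_path(config: Mapping[str, Any], key: str) -> Path:
    path = Path(_require(config, key))
    if not path.exists():
        raise ConfigError(f"config key {key!r}: path {path} does not exist")
    return path


def _setup_logging(out_dir: Path) -> logging.FileHandler:
    handler = logging.FileHandler(out_dir / "pipeline.log", mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    return handler


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def run_biodosimeter(config: Mapping[str, Any], out_dir) -> dict:
    """Radiation-quality biomarker screen; returns the run manifest.

    Config keys: ontology, root_term, selection, annotations (+ dialect),
    ortholog_maps, reference, ppi_edges; optional leaf_categories, min_score,
    min_clique_size, top_n; optional counterpart lookup inputs
    (counterpart_groups, query_idmap, target_idmap, target_taxon).
    """
    obo_path = _require_path(config, "ontology")
    selection_path = _require_path(config, "selection")
    annotations_path = _require_path(config, "annotations")
    maps_path = _require_path(config, "ortholog_maps")
    edges_path = _require_path(config, "ppi_edges")
    root = str(_require(config, "root_term"))
    reference = str(_require(config, "reference"))
    min_score = int(config.get("min_score", 400))
    min_clique_size = int(config.get("min_clique_size", 3))
    top_n = int(config.get("top_n", 10))

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = _setup_logging(out)
    manifest: dict[str, Any] = {
        "pipeline": "biodosimeter",
        "parameters": {
            "root_term": root,
            "reference": reference,
            "min_score": min_score,
            "min_clique_size": min_clique_size,
            "top_n": top_n,
        },
        "stages": {},
    }
    try:
        dag = load_obo(obo_path)
        curated = load_selection_tsv(selection_path)
        selection = select_terms(dag, root, curated)
        log.info("ontology: %d terms, selection of %d", len(dag.terms), len(selection))
        manifest["stages"]["ontology"] = {
            "n_terms": len(dag.terms),
            "n_selected": len(selection),
            "n_uncovered_descendants": len(selection.uncovered),
        }

        sets = load_annotations(annotations_path, config.get("dialect", "tsv"))
        maps = load_ortholog_maps(maps_path)
        projected, report = project_to_reference(sets, maps, reference, selection)
        log.info(
            "projection: %d annotation lists -> %d projected records "
            "(%d unmapped source genes dropped)",
            len(sets), len(projected), report.dropped_unmapped,
        )
        manifest["stages"]["projection"] = {
            "n_annotation_lists": len(sets),
            "n_species": len({s.species for s in sets}),
            "n_projected": len(projected),
            "dropped_unmapped": report.dropped_unmapped,
            "skipped_terms": report.skipped_terms,
        }
        mult = multiplicity(projected)
        _write_tsv(mult, out / "multiplicity.tsv")

        family: dict[str, set[str]] = {}
        for p in projected:
            family.setdefault(p.category, set()).add(p.reference_gene)
        part = partition(family)
        leaf = list(config.get(
            "leaf_categories", ["X-ray", "gamma-ray", "UV-A", "UV-B", "UV-C"]
        ))
        leaf = [c for c in leaf if c in part.categories]
        excl = exclusive_genes(part, leaf)
        (out / "venn_cells.json").write_text(part.to_json(), encoding="utf-8")
        cell_rows = [
            {"cell": "&".join(sorted(subset)), "gene": gene}
            for subset, genes in part.cells.items()
            for gene in sorted(genes)
        ]
        _write_tsv(
            pd.DataFrame(cell_rows, columns=["cell", "gene"]).sort_values(
                ["cell", "gene"], ignore_index=True
            ),
            out / "venn_cells.tsv",
        )
        n_excl = sum(len(s) for s in excl.exclusive.values())
        log.info("setops: %d exclusive genes, %d parent-only", n_excl, len(excl.parent_only))
        manifest["stages"]["setops"] = {
            "n_cells": len(part.cells),
            "universe": len(part.universe),
            "n_exclusive": n_excl,
            "n_parent_only": len(excl.parent_only),
        }

        net = load_edges(edges_path, min_score=min_score)
        scores = clique_node_scores(net, min_size=min_clique_size)
        _write_tsv(scores, out / "node_scores.tsv")
        hubs = select_hub_candidates(
            scores, {c: excl.exclusive[c] for c in leaf}, top_n=top_n
        )
        manifest["stages"]["network"] = {
            "n_nodes": len(net.nodes),
            "n_edges": net.n_edges,
            "shortlist": {c: len(v) for c, v in hubs.items()},
        }

        shortlist = {g for genes in hubs.values() for g in genes}
        node_scores = {
            row.node: float(row.weighted_degree) for row in scores.itertuples()
        }
        ranking = rank_candidates(projected, node_scores, shortlist)
        ranking = ranking[ranking["category"].isin(leaf) | (ranking["category"] == "")]
        _write_tsv(ranking, out / "candidates.tsv")
        manifest["stages"]["ranking"] = {"n_rows": int(len(ranking))}

        if "counterpart_groups" in config:
            groups = load_orthogroups(_require_path(config, "counterpart_groups"))
            qmap = load_idmap(
                _require_path(config, "query_idmap"), str(_require(config, "query_taxon"))
            )
            tmap = load_idmap(
                _require_path(config, "target_idmap"), str(_require(config, "target_taxon"))
            )
            counterparts = find_counterpart_orthologs(
                shortlist, groups, qmap, tmap, tmap.taxon
            )
            _write_tsv(counterparts, out / "counterparts.tsv")
            manifest["stages"]["counterparts"] = {"n_rows": int(len(counterparts))}

        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8"
        )
        return manifest
    finally:
        log.removeHandler(handler)
        handler.close()


def run_repair_comparison(config: Mapping[str, Any], out_dir) -> dict:
    """Cross-taxon repair-mechanism comparison; returns the run manifest.

    Config keys: ontology, root_term, selection, annotations (TSV with the
    two taxa as 'species'), orthogroups, taxon_a, taxon_b; optional
    expansion_depth {0,1} and orth_count_rule {pair,group}.
    """
    obo_path = _require_path(config, "ontology")
    selection_path = _require_path(config, "selection")
    annotations_path = _require_path(config, "annotations")
    groups_path = _require_path(config, "orthogroups")
    root = str(_require(config, "root_term"))
    taxon_a = str(_require(config, "taxon_a"))
    taxon_b = str(_require(config, "taxon_b"))
    depth = int(config.get("expansion_depth", 1))
    rule = str(config.get("orth_count_rule", "pair"))

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = _setup_logging(out)
    manifest: dict[str, Any] = {
        "pipeline": "repair_comparison",
        "parameters": {
            "root_term": root,
            "taxon_a": taxon_a,
            "taxon_b": taxon_b,
            "expansion_depth": depth,
            "orth_count_rule": rule,
        },
        "stages": {},
    }
    try:
        dag = load_obo(obo_path)
        curated = load_selection_tsv(selection_path)
        selection = select_terms(dag, root, curated)
        manifest["stages"]["ontology"] = {
            "n_terms": len(dag.terms),
            "n_selected": len(selection),
        }

        sets = load_annotations(annotations_path, config.get("dialect", "tsv"))
        groups = load_orthogroups(groups_path)
        per_mech: dict[str, dict[str, set[str]]] = {}
        for aset in sets:
            mech = selection.category_of(aset.term_id)
            if mech is None or aset.species not in (taxon_a, taxon_b):
                continue
            per_mech.setdefault(mech, {taxon_a: set(), taxon_b: set()})
            per_mech[mech][aset.species].update(aset.genes)

        results = []
        sizes: dict[str, tuple[int, int]] = {}
        pair_rows, new_rows = [], []
        for mech in sorted(per_mech):
            ann_a, ann_b = per_mech[mech][taxon_a], per_mech[mech][taxon_b]
            res = run_transfer(
                ann_a, ann_b, groups, taxon_a, taxon_b,
                expansion_depth=depth, mechanism=mech,
            )
            results.append(res)
            sizes[mech] = (len(ann_a), len(ann_b))
            pair_rows.extend(
                {"mechanism": mech, "gene_A": a, "gene_B": b}
                for a, b in sorted(res.pairs)
            )
            new_rows.extend(
                {"mechanism": mech, "taxon": taxon_a, "gene": g, "hop": 0}
                for g in sorted(res.new_A)
            )
            new_rows.extend(
                {"mechanism": mech, "taxon": taxon_b, "gene": g, "hop": 0}
                for g in sorted(res.new_B)
            )
            direct = {(taxon_a, g) for g in res.new_A} | {(taxon_b, g) for g in res.new_B}
            new_rows.extend(
                {"mechanism": mech, "taxon": t, "gene": g, "hop": 1}
                for t, g in sorted(res.expansion_new - direct)
            )
        _write_tsv(
            pd.DataFrame(pair_rows, columns=["mechanism", "gene_A", "gene_B"]),
            out / "pairs.tsv",
        )
        _write_tsv(
            pd.DataFrame(new_rows, columns=["mechanism", "taxon", "gene", "hop"]),
            out / "new_genes.tsv",
        )
        summary = summarize(results, sizes, orth_count_rule=rule)
        _write_tsv(summary, out / "summary.tsv")
        manifest["stages"]["transfer"] = {
            "n_groups": len(groups),
            "n_mechanisms": len(results),
            "n_pairs": len(pair_rows),
            "n_new": len(new_rows),
        }
        log.info("transfer: %d mechanisms, %d pairs, %d new genes",
                 len(results), len(pair_rows), len(new_rows))

        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8"
        )
        return manifest
    finally:
        log.removeHandler(handler)
        handler.close()
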