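"""Ontology-DAG subtree coverage: how much of each top-level subcategory
of an ontology is recovered by a species' annotation set, and how two
species compare.

Two counting modes are supported because "coverage of a sub-hierarchy"
is genuinely ambiguous:

* ``children`` (default): the units under a start term are its direct
  children; a unit counts as recovered for a species if the unit itself
  or any term in its subtree carries at least one direct annotation.
* ``terms``: the units are every term in the subtree below the start
  term; a unit is recovered only if directly annotated.

Multi-parent terms may be counted under several subcategories — a term
genuinely belongs to each of its parents' subtrees, so no deduplication
is applied across rows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .seqio import OntologyDag

MODES = ("children", "terms")


@dataclass(frozen=True)
class SubtreeCoverage:
    start_term: str
    mode: str
    n_units_total: int
    n_units_recovered: dict[str, int]  # per species


def descendants(dag: OntologyDag, term_id: str) -> set[str]:
    """All non-obsolete terms strictly below ``term_id`` (transitive
    closure of reverse is_a edges)."""
    dag.term(term_id)  # raises for unknown terms
    below = nx.ancestors(dag.graph, term_id)  # nodes with a path *to* term_id
    return {t for t in below if not dag.term(t).obsolete}


def _recovered_units(
    dag: OntologyDag, annotated: set[str], start_term: str, mode: str
) -> tuple[set[str], set[str]]:
    """(units, recovered units) under ``start_term`` for one species."""
    if mode == "children":
        units = dag.children(start_term)
        recovered = {
            u for u in units if (annotated & ({u} | descendants(dag, u)))
        }
    elif mode == "terms":
        units = descendants(dag, start_term)
        recovered = units & annotated
    else:
        raise ValueError(f"unknown counting mode {mode!r}; expected one of {MODES}")
    return units, recovered


def subtree_coverage(
    dag: OntologyDag,
    annotations: Mapping[str, Iterable[str]],
    start_term: str,
    mode: str = "children",
) -> SubtreeCoverage:
    """Coverage of the sub-hierarchy under ``start_term``.

    ``annotations`` maps species name -> directly annotated term ids.
    Annotations to the start term itself belong to no child unit and are
    ignored here (they carry no within-subcategory location). Obsolete
    terms contribute to no totals and no recoveries.
    """
    recovered_counts: dict[str, int] = {}
    units: set[str] = set()
    for species, terms in annotations.items():
        annotated = {t for t in terms if t in dag and not dag.term(t).obsolete}
        annotated.discard(start_term)
        units, recovered = _recovered_units(dag, annotated, start_term, mode)
        recovered_counts[species] = len(recovered)
    if not annotations:
        units, _ = _recovered_units(dag, set(), start_term, mode)
    return SubtreeCoverage(
        start_term=start_term,
        mode=mode,
        n_units_total=len(units),
        n_units_recovered=recovered_counts,
    )


def compare_species(
    dag: OntologyDag,
    annotations_a: Iterable[str],
    annotations_b: Iterable[str],
    namespace: str,
    mode: str = "children",
    species_names: tuple[str, str] = ("A", "B"),
) -> pd.DataFrame:
    """Per-subcategory coverage comparison of two annotation sets.

    One row per direct child of the namespace root, with the unit total,
    each species' recovered count, and a four-way classification:
    ``both`` / ``<A>_only`` / ``<B>_only`` / ``neither``.
    """
    if len(dag) == 0:
        raise ValueError("empty ontology")
    roots = dag.roots(namespace)
    if not roots:
        raise ValueError(f"no root term found for namespace {namespace!r}")
    name_a, name_b = species_names
    rows = []
    for root in roots:
        for child in sorted(dag.children(root)):
            cov = subtree_coverage(
                dag, {name_a: annotations_a, name_b: annotations_b}, child, mode
            )
            ra = cov.n_units_recovered[name_a]
            rb = cov.n_units_recovered[name_b]
            if ra and rb:
                category = "both"
            elif ra:
                category = f"{name_a}_only"
            elif rb:
                category = f"{name_b}_only"
            else:
                category = "neither"
            rows.append(
                {
                    "start_term": child,
                    "name": dag.term(child).name,
                    "n_units_total": cov.n_units_total,
                    f"recovered_{name_a}": ra,
                    f"recovered_{name_b}": rb,
                    "category": category,
                }
            )
    return pd.DataFrame(rows)
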