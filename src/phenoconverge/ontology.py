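"""Phenotype-ontology handling: DAG parsing, ancestor propagation, subterms.

Phenotype ontologies (the Human Phenotype Ontology and the Mammalian
Phenotype Ontology) are hierarchies in which specific child terms sit
underneath broader parent terms; a patient annotated with a specific term
implicitly carries every ancestor of that term.  This module provides the
directed-acyclic-graph container used throughout the pipeline, the upward
propagation ("imputation") of patient terms, subterm enumeration for the
subterm-restricted similarity analysis, and the configured mapping from
human phenotype terms to model-organism overarching categories.

Only ``is_a`` edges are honoured; other OBO relationship types are
ignored, and obsolete terms are dropped at parse time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

__all__ = [
    "OntologyDAG",
    "CategoryMap",
    "OntologyError",
    "parse_obo",
    "propagate_ancestors",
    "proper_descendants",
    "hpo_to_mpo_category",
    "load_category_map",
]


class OntologyError(ValueError):
    """Raised for structural problems: cycles, missing parents, unknown terms."""


@dataclass
class OntologyDAG:
    """Term hierarchy with is_a edges pointing from child to parent.

    Parameters
    ----------
    term_ids : set of str
        All non-obsolete term identifiers.
    labels : dict
        Term id -> human-readable name.
    is_a_edges : set of (child, parent) pairs
        The child-to-parent relation; acyclic.
    alt_ids : dict
        Alias id -> canonical id (from OBO ``alt_id`` lines).
    """

    term_ids: set[str]
    labels: dict[str, str]
    is_a_edges: set[tuple[str, str]]
    alt_ids: dict[str, str] = field(default_factory=dict)
    _parents: dict[str, set[str]] = field(init=False, repr=False)
    _children: dict[str, set[str]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._parents = {t: set() for t in self.term_ids}
        self._children = {t: set() for t in self.term_ids}
        for child, parent in self.is_a_edges:
            if child not in self.term_ids or parent not in self.term_ids:
                raise OntologyError(
                    f"edge ({child}, {parent}) references a term not in the ontology"
                )
            self._parents[child].add(parent)
            self._children[parent].add(child)
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        g = nx.DiGraph(self.is_a_edges)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise OntologyError(f"is_a cycle detected involving term {cycle[0][0]!r}")

    @property
    def roots(self) -> set[str]:
        return {t for t in self.term_ids if not self._parents[t]}

    def resolve(self, term: str) -> str:
        """Resolve an alias (alt_id) to the canonical id; identity otherwise."""
        return self.alt_ids.get(term, term)

    def parents(self, term: str) -> set[str]:
        return set(self._parents[self.resolve(term)])

    def children(self, term: str) -> set[str]:
        return set(self._children[self.resolve(term)])

    def __contains__(self, term: str) -> bool:
        return self.resolve(term) in self.term_ids

    def __len__(self) -> int:
        return len(self.term_ids)


def parse_obo(path) -> OntologyDAG:
    """Parse an OBO 1.2 flat file into an :class:`OntologyDAG`.

    Obsolete terms are excluded; only ``is_a`` relationships are kept.
    A parent referenced by an ``is_a`` line but never defined in a
    ``[Term]`` stanza is a hard error, as is any cycle.
    """
    graph = obonet.read_obo(path, ignore_obsolete=True)
    # obonet materialises referenced-but-undefined parents as bare nodes
    # with an empty attribute dict; treat those as missing definitions.
    missing = sorted(n for n, d in graph.nodes(data=True) if not d)
    if missing:
        raise OntologyError(f"is_a references to undefined term ids: {missing}")
    term_ids = set(graph.nodes)
    labels = {n: d.get("name", n) for n, d in graph.nodes(data=True)}
    edges = {(c, p) for c, p, key in graph.edges(keys=True) if key == "is_a"}
    alt_ids: dict[str, str] = {}
    for n, d in graph.nodes(data=True):
        for alias in d.get("alt_id", []):
            alt_ids[alias] = n
    return OntologyDAG(term_ids=term_ids, labels=labels, is_a_edges=edges, alt_ids=alt_ids)


def propagate_ancestors(dag: OntologyDAG, direct: Iterable[str]) -> set[str]:
    """Close a set of directly-assigned terms under the parent relation.

    Returns ``direct`` plus every ancestor reachable through is_a edges
    (the imputation of more general terms from the specific terms
    recorded for a patient).  Idempotent and monotone.
    """
    direct = {dag.resolve(t) for t in direct}
    unknown = sorted(t for t in direct if t not in dag.term_ids)
    if unknown:
        raise OntologyError(f"unknown term ids: {unknown}")
    closed: set[str] = set()
    stack = list(direct)
    while stack:
        term = stack.pop()
        if term in closed:
            continue
        closed.add(term)
        stack.extend(dag._parents[term] - closed)
    return closed


def proper_descendants(dag: OntologyDAG, term: str) -> set[str]:
    """All terms whose ancestor closure contains ``term``, excluding itself.

    These are the subterms used when the similarity analysis is restricted
    to finer-grained phenotypes beneath a group-defining term.
    """
    term = dag.resolve(term)
    if term not in dag.term_ids:
        raise OntologyError(f"unknown term id: {term}")
    out: set[str] = set()
    stack = list(dag._children[term])
    while stack:
        t = stack.pop()
        if t in out:
            continue
        out.add(t)
        stack.extend(dag._children[t] - out)
    return out


@dataclass
class CategoryMap:
    """Configured mapping of terms to model-organism overarching categories.

    ``mpo_to_category`` assigns each model-phenotype term to exactly one
    overarching category; ``hpo_to_category`` gives, for a human phenotype
    term, the single most relevant category.  Both are supplied as input
    tables — there is no algorithm here to infer relevance.
    """

    mpo_to_category: dict[str, str]
    hpo_to_category: dict[str, str]

    @property
    def categories(self) -> set[str]:
        return set(self.mpo_to_category.values()) | set(self.hpo_to_category.values())


def hpo_to_mpo_category(term: str, category_map: CategoryMap) -> str | None:
    """Most relevant overarching category for a human phenotype term.

    Returns None when the term is unmapped; callers skip the group for the
    model-organism enrichment engine in that case.
    """
    cat = category_map.hpo_to_category.get(term)
    if cat is None:
        logger.debug("phenotype term %s has no overarching-category mapping", term)
    return cat


def load_category_map(mpo_path, hpo_path) -> CategoryMap:
    """Load the two two-column TSVs (term_id, category) of a CategoryMap."""

    def _read(path) -> dict[str, str]:
        out: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                term, cat = line.split("\t")[:2]
                if term in out and out[term] != cat:
                    raise OntologyError(f"term {term} mapped to two categories")
                out[term] = cat
        return out

    return CategoryMap(mpo_to_category=_read(mpo_path), hpo_to_category=_read(hpo_path))
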