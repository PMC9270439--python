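"""Ontology DAG: parsing, relatives, depth.

Wraps an OBO-format ontology (parsed with obonet) as a directed acyclic
graph of terms with typed parent edges (is_a, and optionally part_of).
Feature construction and the siblings training policy need fast access to
parents, children, siblings, uncles, ancestors and descendants, all
restricted to a single namespace; reporting needs term depth (shortest
directed path to the namespace root).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

_NAMESPACE_ALIASES = {
    "biological_process": "BP",
    "cellular_component": "CC",
    "molecular_function": "MF",
    "BP": "BP",
    "CC": "CC",
    "MF": "MF",
}

_RELATIONS = ("parents", "children", "siblings", "uncles", "ancestors", "descendants")


class OntologyError(ValueError):
    """Raised for malformed ontologies or unknown term lookups."""


@dataclass
class OntologyGraph:
    """DAG of terms with typed child -> parent edges and per-namespace roots."""

    terms: set[str]
    parent_edges: dict[str, set[tuple[str, str]]]  # child -> {(parent, relation)}
    namespace: dict[str, str]  # term -> BP | CC | MF
    roots: dict[str, str]  # namespace -> root term
    _children: dict[str, set[str]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._children = {t: set() for t in self.terms}
        for child, ps in self.parent_edges.items():
            for parent, _rel in ps:
                self._children[parent].add(child)

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        edges: list[tuple[str, str]],
        namespace: str = "BP",
        relation: str = "is_a",
    ) -> "OntologyGraph":
        """Build a single-namespace graph from (child, parent) pairs."""
        terms = {t for e in edges for t in e}
        parent_edges: dict[str, set[tuple[str, str]]] = {t: set() for t in terms}
        for child, parent in edges:
            parent_edges[child].add((parent, relation))
        ns = {t: namespace for t in terms}
        roots = sorted(t for t in terms if not parent_edges[t])
        if len(roots) != 1:
            raise OntologyError(
                f"expected exactly one root, found {roots!r}"
            )
        graph = cls(terms, parent_edges, ns, {namespace: roots[0]})
        graph._check_acyclic()
        return graph

    def _check_acyclic(self) -> None:
        g = nx.DiGraph(
            (c, p) for c, ps in self.parent_edges.items() for p, _ in ps
        )
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            return
        raise OntologyError(f"ontology contains a cycle through {cycle[0][0]!r}")

    # -- queries -----------------------------------------------------------

    def _require(self, term: str) -> None:
        if term not in self.terms:
            raise OntologyError(f"unknown term: {term!r}")

    def parents(self, term: str) -> set[str]:
        self._require(term)
        return {p for p, _ in self.parent_edges.get(term, set())}

    def children(self, term: str) -> set[str]:
        self._require(term)
        return set(self._children.get(term, set()))

    def root_of(self, term: str) -> str:
        self._require(term)
        return self.roots[self.namespace[term]]

    def is_root(self, term: str) -> bool:
        self._require(term)
        return self.roots.get(self.namespace[term]) == term


def relatives(graph: OntologyGraph, term: str, relation: str) -> set[str]:
    """Relatives of a term, namespace-restricted, never including the term.

    siblings: children of any parent, minus the term.  uncles: siblings of
    any parent.  ancestors/descendants: transitive closures excluding the
    term itself.
    """
    graph._require(term)
    if relation not in _RELATIONS:
        raise OntologyError(f"unknown relation: {relation!r}")
    if relation == "parents":
        return graph.parents(term)
    if relation == "children":
        return graph.children(term)
    if relation == "siblings":
        sibs: set[str] = set()
        for p in graph.parents(term):
            sibs |= graph.children(p)
        sibs.discard(term)
        return sibs
    if relation == "uncles":
        uncles: set[str] = set()
        for p in graph.parents(term):
            uncles |= relatives(graph, p, "siblings")
        return uncles
    # transitive closures via BFS
    step = graph.parents if relation == "ancestors" else graph.children
    seen: set[str] = set()
    frontier = step(term)
    while frontier:
        seen |= frontier
        frontier = {x for t in frontier for x in step(t)} - seen
    seen.discard(term)
    return seen


def term_depth(graph: OntologyGraph, term: str, longest: bool = False) -> int:
    """Length of the shortest (default) or longest directed path to the root.

    The namespace root has depth 0.
    """
    graph._require(term)
    root = graph.root_of(term)
    if term == root:
        return 0
    # BFS upward for shortest; DP over ancestors for longest
    if not longest:
        depth = 0
        frontier = {term}
        seen: set[str] = set()
        while frontier:
            if root in frontier:
                return depth
            depth += 1
            seen |= frontier
            frontier = {p for t in frontier for p in graph.parents(t)} - seen
        raise OntologyError(f"term {term!r} is not connected to root {root!r}")
    memo: dict[str, int] = {root: 0}

    def _depth(t: str) -> int:
        if t in memo:
            return memo[t]
        ps = graph.parents(t)
        if not ps:
            raise OntologyError(f"term {t!r} is not connected to root {root!r}")
        memo[t] = 1 + max(_depth(p) for p in ps)
        return memo[t]

    return _depth(term)


def parse_obo(
    obo_file: str | Path, include_part_of: bool = True
) -> OntologyGraph:
    """Parse an OBO 1.2/1.4 file into an :class:`OntologyGraph`.

    Obsolete terms are dropped (obonet's default).  ``is_a`` edges are
    always kept; ``part_of`` edges are kept when ``include_part_of`` is
    true, since true-path propagation conventionally traverses them.
    Cross-namespace edges are dropped.  Terms left with no hierarchical
    parent and no children in their namespace, other than the root, are
    dropped with a warning.
    """
    g = obonet.read_obo(obo_file)
    namespace: dict[str, str] = {}
    for node, data in g.nodes(data=True):
        ns = _NAMESPACE_ALIASES.get(data.get("namespace", ""), None)
        if ns is None:
            ns = "BP"  # single-namespace toy ontologies omit the field
        namespace[node] = ns

    keep_rel = {"is_a"} | ({"part_of"} if include_part_of else set())
    parent_edges: dict[str, set[tuple[str, str]]] = {t: set() for t in g.nodes}
    for child, parent, rel in g.edges(keys=True):
        if rel not in keep_rel:
            continue
        if namespace[child] != namespace[parent]:
            continue
        parent_edges[child].add((parent, rel))

    terms = set(g.nodes)
    # identify roots: parentless terms per namespace
    roots: dict[str, str] = {}
    for ns in sorted(set(namespace.values())):
        candidates = sorted(
            t for t in terms if namespace[t] == ns and not parent_edges[t]
        )
        # drop parentless, childless orphans (e.g. part_of-only terms with
        # part_of disabled); the true root keeps its children
        children_count = {t: 0 for t in candidates}
        for c, ps in parent_edges.items():
            for p, _ in ps:
                if p in children_count:
                    children_count[p] += 1
        connected = [t for t in candidates if children_count[t] > 0]
        orphans = [t for t in candidates if children_count[t] == 0]
        for t in orphans:
            logger.warning("dropping orphan term %s (no hierarchical parent)", t)
            terms.discard(t)
            parent_edges.pop(t, None)
            namespace.pop(t, None)
        if len(connected) != 1:
            raise OntologyError(
                f"namespace {ns}: expected one root, found {connected!r}"
            )
        roots[ns] = connected[0]

    graph = OntologyGraph(terms, parent_edges, namespace, roots)
    graph._check_acyclic()
    return graph


def write_graph_summary(graph: OntologyGraph, path: str | Path) -> None:
    """Summary TSV: term, namespace, depth, n_parents."""
    with open(path, "w") as fh:
        fh.write("# term\tnamespace\tdepth\tn_parents\n")
        for t in sorted(graph.terms):
            fh.write(
                f"{t}\t{graph.namespace[t]}\t{term_depth(graph, t)}\t"
                f"{len(graph.parents(t))}\n"
            )
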