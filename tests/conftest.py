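"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import random

import numpy as np
import pytest

from funcland import (
    AnnotationStore,
    GenomeModel,
    OntologyGraph,
    build_genome_model,
)


# ---------------------------------------------------------------------------
# Toy ontologies
# ---------------------------------------------------------------------------


@pytest.fixture
def chain_graph() -> OntologyGraph:
    """R -> A -> B."""
    return OntologyGraph.from_edges([("A", "R"), ("B", "A")])


@pytest.fixture
def diamond_graph() -> OntologyGraph:
    """R with children A, C; B child of both A and C."""
    return OntologyGraph.from_edges(
        [("A", "R"), ("C", "R"), ("B", "A"), ("B", "C")]
    )


@pytest.fixture
def tree_graph() -> OntologyGraph:
    """R children A, C; A child B; C child D."""
    return OntologyGraph.from_edges(
        [("A", "R"), ("C", "R"), ("B", "A"), ("D", "C")]
    )


@pytest.fixture
def two_level_tree() -> OntologyGraph:
    """R children A, C; A children B, D (siblings/uncles exercises)."""
    return OntologyGraph.from_edges(
        [("A", "R"), ("C", "R"), ("B", "A"), ("D", "A")]
    )


def random_dag(rng: random.Random, n_terms: int) -> OntologyGraph:
    """Random rooted DAG: term i gets 1-2 parents among earlier terms."""
    names = [f"t{i}" for i in range(n_terms)]
    edges = []
    for i in range(1, n_terms):
        parents = rng.sample(names[:i], k=min(i, rng.choice([1, 1, 2])))
        for p in parents:
            edges.append((names[i], p))
    return OntologyGraph.from_edges(edges)


# ---------------------------------------------------------------------------
# Toy genomes
# ---------------------------------------------------------------------------


def linear_model(n: int, arm: str = "c1", prefix: str = "g") -> GenomeModel:
    """Single-arm genome of n genes in rank order g00, g01, ..."""
    width = len(str(n))
    return build_genome_model(
        [
            (f"{prefix}{i:0{width}d}", arm, None, (i + 1) * 100, "+")
            for i in range(n)
        ]
    )


def store_from(assoc: dict[str, set[str]], propagated: bool = True) -> AnnotationStore:
    return AnnotationStore(
        {g: set(ts) for g, ts in assoc.items()}, propagated=propagated
    )


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------


def brute_enrichment(
    model: GenomeModel, store: AnnotationStore, term: str, gene: str, w: int
):
    """O(N) recount of (k/n)/(M/N), written independently of the package's
    window/prefix-sum machinery."""
    arm_id, rank = model.index[gene]
    arm = dict(model.arms)[arm_id]
    annotated = [term in store.assoc.get(g, set()) for g in arm]
    N = len(arm)
    M = sum(annotated)
    window_idx = [
        i
        for i in range(len(arm))
        if i != rank and abs(i - rank) <= w
    ]
    n = len(window_idx)
    k = sum(annotated[i] for i in window_idx)
    if n == 0:
        return None
    if M == 0:
        return 0.0
    return (k / n) / (M / N)


def brute_hierarchical_prf(
    truth: dict[str, set[str]],
    predicted: dict[str, set[str]],
    root: str,
):
    """Direct set-arithmetic hPrec/hRec/hF1 with the root added to both
    sides of every gene."""
    inter = 0
    p_total = 0
    t_total = 0
    for g in truth:
        P = set(predicted.get(g, set())) | {root}
        T = set(truth[g]) | {root}
        inter += len(P & T)
        p_total += len(P)
        t_total += len(T)
    hprec = inter / p_total if p_total else 0.0
    hrec = inter / t_total if t_total else 0.0
    hf1 = 2 * hprec * hrec / (hprec + hrec) if hprec + hrec > 0 else 0.0
    return hprec, hrec, hf1


def brute_ancestors(graph: OntologyGraph, term: str) -> set[str]:
    """Fixed point of repeated parent expansion."""
    closure: set[str] = set(graph.parents(term))
    while True:
        grown = set(closure)
        for t in closure:
            grown |= graph.parents(t)
        if grown == closure:
            break
        closure = grown
    closure.discard(term)
    return closure


def random_instance(seed: int, n_genes: int = 12, n_terms: int = 8):
    """Random (graph, model, leaf store) triple for oracle comparisons."""
    rng = random.Random(seed)
    graph = random_dag(rng, n_terms)
    model = linear_model(n_genes)
    assoc = {}
    terms = sorted(graph.terms)
    for g in model.genes:
        n_ann = rng.randint(0, min(3, len(terms)))
        assoc[g] = set(rng.sample(terms, n_ann)) if n_ann else set()
    return graph, model, AnnotationStore(assoc, propagated=False)
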