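"""Functional Landscape Arrays (FLAs).

The FLA of a gene, relative to a target term, is a matrix of local
enrichment values with one row per window half-width and one column per
term related to the target.  It summarises the functional composition of
the gene's chromosomal neighbourhood at several scales and is the only
predictive feature the classifiers see.  FLAs are always computed from a
masked store in which evaluation genes carry no annotations, so no label
information from held-out genes can leak into features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .annotations import AnnotationStore
from .enrichment import DEFAULT_HALF_WIDTHS, EnrichmentEngine
from .genome import GenomeModel
from .ontology import OntologyGraph, relatives

logger = logging.getLogger(__name__)


class FeatureError(ValueError):
    pass


@dataclass
class FLA:
    gene: str
    target: str
    half_widths: tuple[int, ...]
    terms: tuple[str, ...]
    values: np.ndarray  # shape (len(half_widths), len(terms))


def fla_term_set(
    graph: OntologyGraph, target: str, mode: str = "relatives_down"
) -> list[str]:
    """Ordered term set whose enrichments form the FLA columns.

    relatives_down (default): target, its parents, its siblings and all
    its descendants.  relatives_up: target, its siblings and all its
    ancestors.  Order: target first, then lexicographic — identical for
    every gene sharing a target, which classifier reproducibility
    requires.
    """
    if mode == "relatives_down":
        rest = (
            relatives(graph, target, "parents")
            | relatives(graph, target, "siblings")
            | relatives(graph, target, "descendants")
        )
    elif mode == "relatives_up":
        rest = relatives(graph, target, "siblings") | relatives(
            graph, target, "ancestors"
        )
    else:
        raise FeatureError(f"unknown FLA term-set mode: {mode!r}")
    rest.discard(target)
    return [target] + sorted(rest)


def build_fla(
    model: GenomeModel,
    masked_store: AnnotationStore,
    gene: str,
    target: str,
    graph: OntologyGraph,
    half_widths: tuple[int, ...] = DEFAULT_HALF_WIDTHS,
    mode: str = "relatives_down",
    engine: EnrichmentEngine | None = None,
) -> FLA:
    """FLA for one (gene, target) pair from the masked annotation store.

    A gene on a single-gene arm has no window, hence an all-zero FLA
    (logged).
    """
    terms = fla_term_set(graph, target, mode)
    if engine is None:
        engine = EnrichmentEngine(model, masked_store)
    values = np.zeros((len(half_widths), len(terms)))
    single_arm = False
    for i, w in enumerate(half_widths):
        for j, t in enumerate(terms):
            e = engine.enrichment(gene, t, w)
            if e is None:
                single_arm = True
                e = 0.0
            values[i, j] = e
    if single_arm:
        logger.warning("gene %s sits on a single-gene arm; FLA is all-zero", gene)
    return FLA(gene, target, tuple(half_widths), tuple(terms), values)


def feature_names(
    terms: list[str] | tuple[str, ...],
    half_widths: tuple[int, ...] = DEFAULT_HALF_WIDTHS,
) -> list[str]:
    """Row-major (width-major) flattening order: w5:t1, w5:t2, ..., w10:t1."""
    return [f"w{w}:{t}" for w in half_widths for t in terms]


def build_feature_matrix(
    model: GenomeModel,
    masked_store: AnnotationStore,
    genes: list[str],
    target: str,
    graph: OntologyGraph,
    half_widths: tuple[int, ...] = DEFAULT_HALF_WIDTHS,
    mode: str = "relatives_down",
    engine: EnrichmentEngine | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Genes x flattened-FLA matrix plus feature names.

    Row i is the row-major flattening of build_fla(genes[i], target);
    every row shares the same column layout.
    """
    if not genes:
        raise FeatureError("empty gene list")
    terms = fla_term_set(graph, target, mode)
    if engine is None:
        engine = EnrichmentEngine(model, masked_store)
    out = np.zeros((len(genes), len(half_widths) * len(terms)))
    for i, g in enumerate(genes):
        fla = build_fla(
            model, masked_store, g, target, graph, half_widths, mode, engine
        )
        out[i] = fla.values.ravel()  # row-major: width-major order
    return out, feature_names(terms, tuple(half_widths))
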