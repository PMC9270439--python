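"""Gene-term annotations: reading, true-path propagation, splits, eligibility.

Annotations associate genes with ontology terms.  Under the true-path rule
a gene annotated with a term is implicitly annotated with every ancestor of
that term, so stores are up-propagated before any counting.  Training and
evaluation genes are separated by a uniform random split; a term is
eligible for classification when it annotates enough genes on both sides.
Evaluation genes can be masked: their term sets are emptied but the genes
keep their genome positions, so they still count toward window sizes.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .genome import GenomeModel
from .ontology import OntologyGraph, relatives

logger = logging.getLogger(__name__)


class AnnotationError(ValueError):
    pass


@dataclass
class AnnotationStore:
    """gene -> set-of-terms mapping for a single ontology namespace."""

    assoc: dict[str, set[str]]
    propagated: bool = False
    namespace: str = "BP"

    @property
    def genes(self) -> set[str]:
        return set(self.assoc)

    def terms_for(self, gene: str) -> set[str]:
        return self.assoc.get(gene, set())

    def term_count(self, term: str, genes: Iterable[str] | None = None) -> int:
        """Number of genes (optionally restricted) annotated with term."""
        pool = self.assoc.items() if genes is None else (
            (g, self.assoc.get(g, set())) for g in genes
        )
        return sum(1 for _, ts in pool if term in ts)

    def all_terms(self) -> set[str]:
        out: set[str] = set()
        for ts in self.assoc.values():
            out |= ts
        return out

    def copy(self) -> "AnnotationStore":
        return AnnotationStore(
            {g: set(ts) for g, ts in self.assoc.items()},
            self.propagated,
            self.namespace,
        )


@dataclass(frozen=True)
class Split:
    """Random partition of the genome's genes into train (T) and eval (E)."""

    T: frozenset[str]
    E: frozenset[str]
    seed: int
    fraction: float


def read_annotations(
    path: str | Path,
    graph: OntologyGraph,
    evidence_filter: set[str] | None = None,
    namespace: str | None = None,
) -> AnnotationStore:
    """Read GAF 2.x or two-column TSV (gene_id <tab> term_id).

    GAF rows with a NOT qualifier are dropped; rows whose term is absent
    from the graph are dropped with a logged count; an optional evidence
    filter keeps only the listed GAF evidence codes.  The result is not
    yet propagated.
    """
    assoc: dict[str, set[str]] = {}
    unknown = 0
    usable = 0
    try:
        fh = open(path)
    except OSError as exc:
        raise AnnotationError(f"cannot read annotations: {exc}") from exc
    with fh:
        for line in fh:
            if line.startswith(("!", "#")) or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) >= 15:  # GAF 2.x
                gene, qualifier, term, evidence = f[1], f[3], f[4], f[6]
                if "NOT" in qualifier.split("|"):
                    continue
                if evidence_filter is not None and evidence not in evidence_filter:
                    continue
            elif len(f) >= 2:
                gene, term = f[0], f[1]
            else:
                continue
            if term not in graph.terms:
                unknown += 1
                continue
            if namespace is not None and graph.namespace[term] != namespace:
                continue
            assoc.setdefault(gene, set()).add(term)
            usable += 1
    if unknown:
        logger.warning("dropped %d rows with terms absent from the graph", unknown)
    if usable == 0:
        raise AnnotationError(f"no usable annotation rows in {path}")
    ns = namespace or next(
        iter({graph.namespace[t] for ts in assoc.values() for t in ts})
    )
    return AnnotationStore(assoc, propagated=False, namespace=ns)


def propagate(store: AnnotationStore, graph: OntologyGraph) -> AnnotationStore:
    """Up-propagate under the true-path rule: add all ancestors of each term.

    Idempotent; never removes a term.
    """
    closure_cache: dict[str, set[str]] = {}

    def closure(term: str) -> set[str]:
        if term not in closure_cache:
            if term not in graph.terms:
                raise AnnotationError(f"annotated term not in graph: {term!r}")
            closure_cache[term] = {term} | relatives(graph, term, "ancestors")
        return closure_cache[term]

    assoc = {
        g: set().union(*(closure(t) for t in ts)) if ts else set()
        for g, ts in store.assoc.items()
    }
    return AnnotationStore(assoc, propagated=True, namespace=store.namespace)


def restrict(store: AnnotationStore, genes: Iterable[str]) -> AnnotationStore:
    """Store limited to the listed genes; unannotated genes get empty sets."""
    return AnnotationStore(
        {g: set(store.assoc.get(g, set())) for g in genes},
        store.propagated,
        store.namespace,
    )


def split_train_eval(model: GenomeModel, fraction: float, seed: int) -> Split:
    """Uniform random split of the model's genes into T (train) and E (eval).

    |T| = round(fraction * total) with round-half-even.  Deterministic
    given the seed; no stratification.
    """
    if not 0.0 < fraction < 1.0:
        raise AnnotationError(f"fraction must be in (0,1), got {fraction}")
    genes = sorted(model.index)
    rng = random.Random(seed)
    rng.shuffle(genes)
    n_train = round(fraction * len(genes))
    return Split(
        T=frozenset(genes[:n_train]),
        E=frozenset(genes[n_train:]),
        seed=seed,
        fraction=fraction,
    )


def eligible_terms(
    store: AnnotationStore,
    split: Split,
    graph: OntologyGraph,
    min_T: int = 40,
    min_E: int = 10,
) -> list[str]:
    """Terms with >= min_T annotated genes in T and >= min_E in E.

    Counts use the propagated store.  The namespace root is never
    eligible.  Result sorted by term id.
    """
    if not store.propagated:
        raise AnnotationError("eligible_terms requires a propagated store")
    counts_T: dict[str, int] = {}
    counts_E: dict[str, int] = {}
    for g, ts in store.assoc.items():
        bucket = counts_T if g in split.T else counts_E if g in split.E else None
        if bucket is None:
            continue
        for t in ts:
            bucket[t] = bucket.get(t, 0) + 1
    out = [
        t
        for t in counts_T
        if counts_T[t] >= min_T
        and counts_E.get(t, 0) >= min_E
        and not graph.is_root(t)
    ]
    return sorted(out)


def mask(store: AnnotationStore, hidden_genes: set[str]) -> AnnotationStore:
    """Empty the term sets of hidden genes; the genes stay present.

    Masked genes keep their genome positions and therefore still count
    toward window sizes (n, N) but never toward term counts (k, M).
    """
    out = store.copy()
    for g in hidden_genes:
        out.assoc[g] = set()
    return out


def write_split(split: Split, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# seed={split.seed} fraction={split.fraction}\n")
        fh.write("# gene_id\tset\n")
        for g in sorted(split.T):
            fh.write(f"{g}\tT\n")
        for g in sorted(split.E):
            fh.write(f"{g}\tE\n")


def read_split(path: str | Path) -> Split:
    T, E = set(), set()
    seed, fraction = 0, 0.8
    with open(path) as fh:
        for line in fh:
            if line.startswith("# seed="):
                parts = dict(p.split("=") for p in line[2:].split())
                seed = int(parts["seed"])
                fraction = float(parts["fraction"])
                continue
            if line.startswith("#") or not line.strip():
                continue
            g, s = line.rstrip("\n").split("\t")
            (T if s == "T" else E).add(g)
    return Split(frozenset(T), frozenset(E), seed, fraction)
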