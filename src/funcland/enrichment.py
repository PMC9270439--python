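"""Local enrichment of ontology terms in gene-count windows.

For a focal gene j, term x and window half-width w, the local enrichment is

    E = (k / n) / (M / N)

where N is the number of genes on j's chromosomal arm, M the number of arm
genes annotated with x, n the number of genes in the window around j
(truncated at arm ends, focal gene excluded) and k the number of window
genes annotated with x.  E > 1 means genes carrying x are over-represented
around j relative to the arm background.  The statistic is the ratio
itself, not a significance test.

A functional enrichment map evaluates E at every gene position of every
arm for a set of window half-widths, showing which regions of a genome are
enriched in a term.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .annotations import AnnotationStore
from .genome import GenomeModel, window_members

logger = logging.getLogger(__name__)

#: Window half-widths (genes to each side) used throughout.
DEFAULT_HALF_WIDTHS = (5, 10, 20, 50, 100)

#: Map mode only covers terms annotating at least this many genes.
MAP_MODE_MIN_GENES = 20

#: Sentinel for enrichment on a single-gene arm (window empty, n = 0).
UNDEFINED = None


class EnrichmentError(ValueError):
    pass


@dataclass(frozen=True)
class WindowCount:
    """Counts underlying one local-enrichment value."""

    N: int  # genes on the arm
    M: int  # arm genes annotated with the term
    n: int  # genes in the window (focal excluded)
    k: int  # window genes annotated with the term
    gene: str
    term: str
    half_width: int

    def __post_init__(self) -> None:
        if not (0 <= self.k <= self.n <= self.N - 1):
            raise EnrichmentError(f"inconsistent counts: {self}")
        if self.k > 0 and self.M == 0:
            raise EnrichmentError(f"k > 0 with M = 0: {self}")


def window_counts(
    model: GenomeModel,
    store: AnnotationStore,
    term: str,
    gene: str,
    w: int,
) -> WindowCount:
    """Count N, M, n, k for one (gene, term, half-width) triple.

    N and M are taken over the focal gene's arm only; n and k over
    window_members (focal excluded, truncated at arm ends).
    """
    arm_id, _ = model.locate(gene)
    arm = model.arm_genes(arm_id)
    members = window_members(model, gene, w)
    M = sum(1 for g in arm if term in store.terms_for(g))
    k = sum(1 for g in members if term in store.terms_for(g))
    return WindowCount(
        N=len(arm), M=M, n=len(members), k=k, gene=gene, term=term, half_width=w
    )


def local_enrichment(counts: WindowCount) -> float | None:
    """(k/n)/(M/N); 0.0 when M = 0; None (logged) when n = 0.

    M = 0 forces k = 0, and "no signal" is the semantically correct
    feature value, so the M = 0 case is defined as 0 rather than NaN.
    A single-gene arm has an empty window (n = 0) and no defined value.
    """
    if counts.n == 0:
        logger.warning(
            "undefined enrichment for %s/%s: empty window (single-gene arm)",
            counts.gene,
            counts.term,
        )
        return UNDEFINED
    if counts.M == 0:
        return 0.0
    return (counts.k / counts.n) / (counts.M / counts.N)


@dataclass
class EnrichmentMap:
    """Per-arm, per-half-width enrichment arrays for one term."""

    term: str
    # arm_id -> {half_width -> array of enrichment values, one per rank}
    values: dict[str, dict[int, np.ndarray]]


class EnrichmentEngine:
    """Prefix-sum accelerated enrichment over a fixed (model, store) pair.

    Per (arm, term) an annotation indicator and its cumulative sum are
    cached, making each window count O(1).  Results are identical to the
    direct counting path.
    """

    def __init__(self, model: GenomeModel, store: AnnotationStore):
        self.model = model
        self.store = store
        self._cache: dict[tuple[str, str], tuple[np.ndarray, np.ndarray, int]] = {}

    def _arm_term(self, arm_id: str, term: str):
        key = (arm_id, term)
        if key not in self._cache:
            genes = self.model.arm_genes(arm_id)
            ind = np.fromiter(
                (term in self.store.terms_for(g) for g in genes),
                dtype=np.int64,
                count=len(genes),
            )
            cs = np.concatenate(([0], np.cumsum(ind)))
            self._cache[key] = (ind, cs, int(ind.sum()))
        return self._cache[key]

    def enrichment(self, gene: str, term: str, w: int) -> float | None:
        arm_id, rank = self.model.locate(gene)
        ind, cs, M = self._arm_term(arm_id, term)
        L = len(ind)
        lo, hi = max(0, rank - w), min(L - 1, rank + w)
        n = hi - lo  # window size minus the focal gene
        if n == 0:
            return UNDEFINED
        if M == 0:
            return 0.0
        k = int(cs[hi + 1] - cs[lo] - ind[rank])
        return (k / n) / (M / L)

    def arm_profile(self, arm_id: str, term: str, w: int) -> np.ndarray:
        """Enrichment at every rank of one arm for one half-width."""
        ind, cs, M = self._arm_term(arm_id, term)
        L = len(ind)
        ranks = np.arange(L)
        lo = np.maximum(0, ranks - w)
        hi = np.minimum(L - 1, ranks + w)
        n = hi - lo
        if L == 1:
            return np.full(1, np.nan)
        if M == 0:
            return np.zeros(L)
        k = cs[hi + 1] - cs[lo] - ind
        return (k / n) / (M / L)


def enrichment_map(
    model: GenomeModel,
    store: AnnotationStore,
    term: str,
    half_widths: tuple[int, ...] = DEFAULT_HALF_WIDTHS,
    map_mode: bool = False,
    min_genes: int = MAP_MODE_MIN_GENES,
) -> EnrichmentMap | None:
    """Enrichment at every gene rank of every arm, per half-width.

    In map mode, terms annotating fewer than ``min_genes`` genes are
    skipped with a notice (returns None).
    """
    total = store.term_count(term)
    if map_mode and total < min_genes:
        logger.info(
            "skipping map for %s: %d annotated genes < floor %d",
            term,
            total,
            min_genes,
        )
        return None
    engine = EnrichmentEngine(model, store)
    values: dict[str, dict[int, np.ndarray]] = {}
    for arm_id, _genes in model.arms:
        values[arm_id] = {
            w: engine.arm_profile(arm_id, term, w) for w in half_widths
        }
    return EnrichmentMap(term=term, values=values)


def write_enrichment_map(
    emap: EnrichmentMap, model: GenomeModel, path: str | Path
) -> None:
    """Long-format TSV: term, arm, 1-based position, gene_id, w, enrichment."""
    with open(path, "w") as fh:
        fh.write("# term\tarm\tposition_1based\tgene_id\tw\tenrichment\n")
        for arm_id, genes in model.arms:
            per_w = emap.values[arm_id]
            for w in sorted(per_w):
                arr = per_w[w]
                for rank, g in enumerate(genes):
                    v = arr[rank]
                    out = "NA" if np.isnan(v) else f"{v:.6g}"
                    fh.write(
                        f"{emap.term}\t{arm_id}\t{rank + 1}\t{g}\t{w}\t{out}\n"
                    )
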