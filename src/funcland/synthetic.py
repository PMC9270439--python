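"""Synthetic genomes and toy ontologies with tunable functional clustering.

Real genomes harbour local clusters of co-expressed, co-regulated or
functionally related genes; this module generates genomes that emulate
exactly that statistical structure — local over-representation of genes
sharing annotations — with a dial (the cluster strength rho) running from
fully random placement (rho = 0) to fully contiguous placement (rho = 1).
Annotations are generated at ontology leaves and up-propagated through
the ordinary propagation path, so every pipeline stage is exercised the
same way as with real data.  A shuffling null destroys the spatial signal
while preserving term frequencies exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .annotations import AnnotationStore
from .genome import GenomeModel, build_genome_model
from .ontology import OntologyGraph

logger = logging.getLogger(__name__)

_MAX_TERMS = 10_000


class SyntheticError(ValueError):
    pass


@dataclass
class SyntheticSpec:
    """Parameters of a clustered synthetic genome.

    terms_per_gene is the expected number of leaf terms per gene (each
    leaf's gene count is Poisson around terms_per_gene * n_genes /
    n_leaves, floored at 2).  cluster_strength rho is the fraction of
    each leaf term's genes placed in contiguous runs; the rest are
    placed uniformly at random.
    """

    n_genes: int = 2000
    n_arms: int = 4
    levels: int = 3
    branching: int = 3
    terms_per_gene: float = 0.6
    cluster_strength: float = 0.8
    cluster_count: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.cluster_strength <= 1.0:
            raise SyntheticError("cluster_strength must lie in [0, 1]")
        if self.n_genes < self.n_arms or self.n_arms < 1:
            raise SyntheticError("need n_genes >= n_arms >= 1")


def make_toy_ontology(
    levels: int,
    branching: int,
    seed: int = 0,
    diamond_rate: float = 0.0,
    namespace: str = "BP",
) -> OntologyGraph:
    """Rooted tree ontology of size sum_l branching^l, optionally with
    extra random diamond edges.

    Term ids encode level and index (T.<level>.<index>); the root is T.0.0.
    Deterministic given the seed.
    """
    if levels < 1 or branching < 1:
        raise SyntheticError("need levels >= 1 and branching >= 1")
    n_terms = sum(branching**level for level in range(levels + 1))
    if n_terms > _MAX_TERMS:
        raise SyntheticError(f"ontology too large: {n_terms} terms")
    rng = np.random.default_rng(seed)
    edges: list[tuple[str, str]] = []
    prev = ["T.0.0"]
    all_terms = ["T.0.0"]
    for level in range(1, levels + 1):
        cur = [f"T.{level}.{i}" for i in range(branching**level)]
        for i, t in enumerate(cur):
            edges.append((t, prev[i // branching]))
        # optional diamond edges: a second parent from the level above
        if diamond_rate > 0 and len(prev) > 1:
            for i, t in enumerate(cur):
                if rng.random() < diamond_rate:
                    alt = prev[int(rng.integers(len(prev)))]
                    if (t, alt) not in edges:
                        edges.append((t, alt))
        all_terms.extend(cur)
        prev = cur
    return OntologyGraph.from_edges(edges, namespace=namespace)


def _leaves(graph: OntologyGraph) -> list[str]:
    return sorted(t for t in graph.terms if not graph.children(t))


def make_clustered_genome(
    spec: SyntheticSpec, graph: OntologyGraph
) -> tuple[GenomeModel, AnnotationStore]:
    """Genome whose leaf-term annotations cluster spatially with strength rho.

    Each leaf term draws a gene count; a fraction rho of its genes go
    into contiguous runs at random arm locations, the rest are placed
    uniformly.  Terms may overlap (a gene can carry several leaf terms).
    The returned store is leaf-level and unpropagated.  Synthesized TSS
    coordinates are rank * 1000 bp so file writers round-trip.
    """
    rng = np.random.default_rng(spec.seed)
    leaves = _leaves(graph)
    ns = graph.namespace[leaves[0]]

    # genes spread evenly over arms
    per_arm = [spec.n_genes // spec.n_arms] * spec.n_arms
    for i in range(spec.n_genes % spec.n_arms):
        per_arm[i] += 1
    width = len(str(spec.n_genes))
    records = []
    arm_slots: list[tuple[str, list[str]]] = []
    gid = 0
    for a, count in enumerate(per_arm):
        arm_id = f"arm{a + 1}"
        ids = []
        for r in range(count):
            gene = f"g{gid:0{width}d}"
            gid += 1
            ids.append(gene)
            records.append((gene, arm_id, None, (r + 1) * 1000, "+"))
        arm_slots.append((arm_id, ids))
    model = build_genome_model(records)

    mean_count = spec.terms_per_gene * spec.n_genes / len(leaves)
    assoc: dict[str, set[str]] = {g: set() for g, *_ in records}
    all_genes = [g for _, ids in arm_slots for g in ids]
    for leaf in leaves:
        n_t = max(2, int(rng.poisson(mean_count)))
        n_t = min(n_t, spec.n_genes)
        n_clustered = int(round(spec.cluster_strength * n_t))
        chosen: set[str] = set()
        if n_clustered > 0:
            runs = np.array_split(np.arange(n_clustered), spec.cluster_count)
            for run in runs:
                run_len = len(run)
                if run_len == 0:
                    continue
                arm_id, ids = arm_slots[int(rng.integers(len(arm_slots)))]
                if run_len > len(ids):
                    raise SyntheticError(
                        f"cluster of {run_len} genes exceeds arm {arm_id} "
                        f"length {len(ids)}"
                    )
                start = int(rng.integers(len(ids) - run_len + 1))
                chosen.update(ids[start : start + run_len])
        n_rest = n_t - n_clustered
        if n_rest > 0:
            extra = rng.choice(len(all_genes), size=n_rest, replace=False)
            chosen.update(all_genes[i] for i in extra)
        for g in chosen:
            assoc[g].add(leaf)
    return model, AnnotationStore(assoc, propagated=False, namespace=ns)


def shuffle_annotations(
    model: GenomeModel, store: AnnotationStore, seed: int
) -> AnnotationStore:
    """Permute annotation sets over gene positions uniformly.

    Destroys spatial clustering; marginal term frequencies are preserved
    exactly (the sets themselves are reassigned, not resampled).
    """
    genes = sorted(model.index)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(genes))
    assoc = {
        genes[i]: set(store.terms_for(genes[perm[i]])) for i in range(len(genes))
    }
    return AnnotationStore(assoc, store.propagated, store.namespace)


# ---------------------------------------------------------------------------
# Writers in the exact dialects the real readers consume
# ---------------------------------------------------------------------------


def write_toy_obo(graph: OntologyGraph, path: str | Path) -> None:
    """Minimal OBO 1.2 serialisation of a toy ontology."""
    ns_long = {"BP": "biological_process", "CC": "cellular_component",
               "MF": "molecular_function"}
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n")
        for t in sorted(graph.terms):
            fh.write(f"\n[Term]\nid: {t}\nname: {t}\n")
            fh.write(f"namespace: {ns_long[graph.namespace[t]]}\n")
            for p, rel in sorted(graph.parent_edges.get(t, set())):
                if rel == "is_a":
                    fh.write(f"is_a: {p} ! {p}\n")
                else:
                    fh.write(f"relationship: {rel} {p} ! {p}\n")


def write_annotation_tsv(store: AnnotationStore, path: str | Path) -> None:
    """Two-column dialect: gene_id <tab> term_id, one row per pair."""
    with open(path, "w") as fh:
        fh.write("# gene_id\tterm_id\n")
        for g in sorted(store.assoc):
            for t in sorted(store.assoc[g]):
                fh.write(f"{g}\t{t}\n")


def write_gene_order_input(model: GenomeModel, path: str | Path) -> None:
    """Four-column genome input dialect: gene_id, chrom(arm), tss, strand."""
    with open(path, "w") as fh:
        fh.write("# gene_id\tchrom\ttss\tstrand\n")
        for arm_id, genes in model.arms:
            for rank, g in enumerate(genes):
                fh.write(f"{g}\t{arm_id}\t{(rank + 1) * 1000}\t+\n")
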