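"""Genome model: ordered strings of protein-coding genes per chromosomal arm.

A genome is represented as a collection of segments (chromosomal arms) in
which protein-coding genes sit one next to the other, without intergenic
regions or overlaps.  A gene's position is the rank of its transcription
start site (TSS) within its arm; the distance between two genes is the
number of genes located between them.  Physical base-pair coordinates are
discarded once the ordering is established.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

#: Sentinel returned by :func:`gene_distance` for genes on different arms.
DIFFERENT_ARMS = None


class GenomeError(ValueError):
    """Raised for malformed genome inputs or unknown gene lookups."""


@dataclass(frozen=True)
class GeneRecord:
    """One input gene prior to ordering."""

    gene_id: str
    chromosome: str
    arm: str | None
    tss: int  # 1-based bp, strand-aware (start for +, end for -)
    strand: str = "+"


@dataclass
class GenomeModel:
    """Ordered gene arrays per arm plus a gene -> (arm, rank) index.

    Invariants: every gene appears in exactly one arm at exactly one rank;
    ranks within an arm are consecutive starting at 0.
    """

    arms: list[tuple[str, list[str]]]
    index: dict[str, tuple[str, int]] = field(repr=False)

    @property
    def n_genes(self) -> int:
        return len(self.index)

    @property
    def genes(self) -> list[str]:
        """All gene ids in arm order."""
        return [g for _, arm_genes in self.arms for g in arm_genes]

    def arm_genes(self, arm_id: str) -> list[str]:
        for aid, genes in self.arms:
            if aid == arm_id:
                return genes
        raise GenomeError(f"unknown arm: {arm_id!r}")

    def locate(self, gene_id: str) -> tuple[str, int]:
        try:
            return self.index[gene_id]
        except KeyError:
            raise GenomeError(f"unknown gene: {gene_id!r}") from None


def build_genome_model(
    gene_records: Iterable[GeneRecord | tuple],
) -> GenomeModel:
    """Order genes into arms by strand-aware TSS coordinate.

    Within each arm genes are sorted by TSS ascending, ties broken by
    gene_id lexicographic.  Intergenic distances are discarded; only the
    order is retained.  Records may be GeneRecord or plain 5-tuples
    (gene_id, chromosome, arm_or_none, tss, strand).
    """
    records = [
        r if isinstance(r, GeneRecord) else GeneRecord(*r) for r in gene_records
    ]
    if not records:
        raise GenomeError("no gene records supplied")
    seen: set[str] = set()
    for r in records:
        if r.gene_id in seen:
            raise GenomeError(f"duplicate gene_id: {r.gene_id!r}")
        seen.add(r.gene_id)
        if r.tss <= 0:
            raise GenomeError(f"non-positive TSS for {r.gene_id!r}: {r.tss}")

    by_arm: dict[str, list[GeneRecord]] = {}
    for r in records:
        arm_id = r.arm if r.arm is not None else r.chromosome
        by_arm.setdefault(arm_id, []).append(r)

    arms: list[tuple[str, list[str]]] = []
    index: dict[str, tuple[str, int]] = {}
    for arm_id in sorted(by_arm):
        ordered = sorted(by_arm[arm_id], key=lambda r: (r.tss, r.gene_id))
        gene_ids = [r.gene_id for r in ordered]
        arms.append((arm_id, gene_ids))
        for rank, g in enumerate(gene_ids):
            index[g] = (arm_id, rank)
    return GenomeModel(arms=arms, index=index)


def window_members(model: GenomeModel, gene: str, half_width: int) -> list[str]:
    """Genes at ranks [r-w, r+w] on the focal gene's arm, focal excluded.

    Truncated at arm boundaries; never crosses arms.  The focal gene is
    excluded so that a gene's own annotation can never leak into its own
    feature values.
    """
    if half_width <= 0:
        raise GenomeError(f"half_width must be positive, got {half_width}")
    arm_id, rank = model.locate(gene)
    genes = model.arm_genes(arm_id)
    lo = max(0, rank - half_width)
    hi = min(len(genes) - 1, rank + half_width)
    return genes[lo:rank] + genes[rank + 1 : hi + 1]


def gene_distance(model: GenomeModel, a: str, b: str) -> int | None:
    """Number of genes strictly between a and b; None across arms.

    Adjacent genes have distance 0.  Symmetric.
    """
    arm_a, ra = model.locate(a)
    arm_b, rb = model.locate(b)
    if arm_a != arm_b:
        return DIFFERENT_ARMS
    if a == b:
        return 0
    return abs(ra - rb) - 1


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_CODING_BIOTYPES = {"protein_coding"}


def _gff3_attributes(field9: str) -> dict[str, str]:
    out = {}
    for part in field9.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def _gtf_attributes(field9: str) -> dict[str, str]:
    out = {}
    for part in field9.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if " " in part:
            k, v = part.split(" ", 1)
            out[k] = v.strip().strip('"')
    return out


def _records_from_rows(rows, centromeres):
    records = []
    for gene_id, chrom, start, end, strand in rows:
        tss = start if strand != "-" else end
        arm = None
        if centromeres and chrom in centromeres:
            arm = f"{chrom}L" if tss < centromeres[chrom] else f"{chrom}R"
        records.append(GeneRecord(gene_id, chrom, arm, tss, strand))
    return records


def read_gff3(
    path: str | Path, centromeres: dict[str, int] | None = None
) -> GenomeModel:
    """Build a model from GFF3 `gene` features with a protein_coding biotype.

    Only protein-coding genes are kept.  If a centromere table
    (chromosome -> bp) is given, each chromosome is split into two arms
    (<chrom>L / <chrom>R); otherwise each chromosome is one arm.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            attrs = _gff3_attributes(f[8])
            biotype = (
                attrs.get("biotype")
                or attrs.get("gene_biotype")
                or attrs.get("gene_type")
            )
            if biotype not in _CODING_BIOTYPES:
                continue
            gene_id = attrs.get("ID") or attrs.get("gene_id")
            if gene_id is None:
                continue
            gene_id = gene_id.removeprefix("gene:")
            rows.append((gene_id, f[0], int(f[3]), int(f[4]), f[6]))
    return build_genome_model(_records_from_rows(rows, centromeres))


def read_gtf(
    path: str | Path, centromeres: dict[str, int] | None = None
) -> GenomeModel:
    """Like :func:`read_gff3` but for GTF attribute syntax."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            attrs = _gtf_attributes(f[8])
            if attrs.get("gene_biotype", attrs.get("gene_type")) not in _CODING_BIOTYPES:
                continue
            gene_id = attrs.get("gene_id")
            if gene_id is None:
                continue
            rows.append((gene_id, f[0], int(f[3]), int(f[4]), f[6]))
    return build_genome_model(_records_from_rows(rows, centromeres))


def read_gene_order_tsv(
    path: str | Path, centromeres: dict[str, int] | None = None
) -> GenomeModel:
    """Read the 4-column dialect: gene_id <tab> chrom <tab> tss <tab> strand."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            gene_id, chrom, tss, strand = line.rstrip("\n").split("\t")[:4]
            tss = int(tss)
            rows.append((gene_id, chrom, tss, tss, strand))
    return build_genome_model(_records_from_rows(rows, centromeres))


def read_centromeres(path: str | Path) -> dict[str, int]:
    """Two-column TSV: chromosome <tab> centromere bp."""
    out = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, bp = line.rstrip("\n").split("\t")[:2]
            out[chrom] = int(bp)
    return out


def write_gene_order(model: GenomeModel, path: str | Path) -> None:
    """Provenance TSV of (arm, position, gene_id); positions are 1-based."""
    with open(path, "w") as fh:
        fh.write("# arm\tposition_1based\tgene_id\n")
        for arm_id, genes in model.arms:
            for rank, g in enumerate(genes):
                fh.write(f"{arm_id}\t{rank + 1}\t{g}\n")
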