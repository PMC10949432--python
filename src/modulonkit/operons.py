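"""Operon clustering by intergenic distance.

Genes are batched by accession, sorted by start coordinate, and scanned
once: a gene joins the current operon when the intergenic gap to the
previous gene (next.start - current.end - 1) is at most the threshold and,
by default, the strands match; otherwise a new operon starts. Coordinates
are 1-based inclusive (GFF3 convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

__all__ = ["GeneRecord", "OperonMap", "cluster_operons", "genes_from_dataframe"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    accession: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"{self.gene_id}: start must be >= 1 (1-based)")
        if self.end < self.start:
            raise ValueError(f"{self.gene_id}: end < start")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")


@dataclass
class OperonMap:
    """A partition of genes into spatially clustered operons."""

    operons: dict[str, list[str]]  # operon_id -> ordered gene ids
    gene_to_operon: dict[str, str]

    def __post_init__(self) -> None:
        flat = [g for members in self.operons.values() for g in members]
        if len(flat) != len(set(flat)):
            raise ValueError("operon map is not a partition: duplicated gene")
        if set(flat) != set(self.gene_to_operon):
            raise ValueError("operon map lookup inconsistent with member lists")

    @property
    def n_operons(self) -> int:
        return len(self.operons)

    def to_frame(self, genes: list[GeneRecord] | None = None) -> pd.DataFrame:
        rows = []
        coords = {g.gene_id: g for g in genes} if genes else {}
        for op_id, members in self.operons.items():
            for g in members:
                row = {"operon_id": op_id, "gene_id": g}
                if g in coords:
                    rec = coords[g]
                    row.update(
                        accession=rec.accession, start=rec.start,
                        end=rec.end, strand=rec.strand,
                    )
                rows.append(row)
        return pd.DataFrame(rows)


def genes_from_dataframe(df: pd.DataFrame) -> list[GeneRecord]:
    return [
        GeneRecord(
            gene_id=str(r.gene_id), accession=str(r.accession),
            start=int(r.start), end=int(r.end), strand=str(r.strand),
        )
        for r in df.itertuples()
    ]


def cluster_operons(
    genes: list[GeneRecord],
    gap_threshold: int = 500,
    require_same_strand: bool = True,
) -> OperonMap:
    """Partition genes into operons by intergenic gap.

    Overlapping genes (negative gap) are treated as gap 0 and joined,
    subject to the strand rule. Operon ids are deterministic:
    ``{accession}_op{ordinal}`` in genomic order.
    """
    if not genes:
        raise ValueError("gene list is empty")
    ids = [g.gene_id for g in genes]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate gene ids")

    operons: dict[str, list[str]] = {}
    gene_to_operon: dict[str, str] = {}
    by_acc: dict[str, list[GeneRecord]] = {}
    for g in genes:
        by_acc.setdefault(g.accession, []).append(g)

    for acc in sorted(by_acc):
        ordered = sorted(by_acc[acc], key=lambda g: (g.start, g.end, g.gene_id))
        ordinal = 0
        current: list[GeneRecord] = []
        for g in ordered:
            if current:
                prev = current[-1]
                gap = g.start - prev.end - 1
                if gap < 0:
                    log.debug("overlapping genes %s/%s: gap %d treated as 0",
                              prev.gene_id, g.gene_id, gap)
                    gap = 0
                same_strand = (not require_same_strand) or g.strand == prev.strand
                if gap <= gap_threshold and same_strand:
                    current.append(g)
                    continue
                ordinal += 1
                op_id = f"{acc}_op{ordinal:03d}"
                operons[op_id] = [x.gene_id for x in current]
                for x in current:
                    gene_to_operon[x.gene_id] = op_id
                current = []
            current.append(g)
        if current:
            ordinal += 1
            op_id = f"{acc}_op{ordinal:03d}"
            operons[op_id] = [x.gene_id for x in current]
            for x in current:
                gene_to_operon[x.gene_id] = op_id
    return OperonMap(operons=operons, gene_to_operon=gene_to_operon)
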