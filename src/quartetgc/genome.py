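"""Gene coordinate maps and homology-hit tables.

Genes are the positional substrate for colinearity analysis: each gene carries
its chromosome, base-pair span (0-based half-open) and an ordinal index along
the chromosome.  Homology hits are all-vs-all protein search results (the
pipeline consumes them; it never runs the search itself).
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
import pyranges as pr


@dataclass(frozen=True)
class GeneRecord:
    """A gene's location: chromosome, ordinal rank and base-pair span."""

    gene_id: str
    chromosome: str
    order_index: int
    start_bp: int
    end_bp: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start_bp >= self.end_bp:
            raise ValueError(
                f"gene {self.gene_id}: start_bp must be < end_bp "
                f"({self.start_bp} >= {self.end_bp})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")


class ChromosomeMap:
    """Genes of one genome indexed by id and ordered along each chromosome.

    ``order_index`` is assigned per chromosome by sorting on ``start_bp``;
    records supplied with explicit indices are validated against that order.
    """

    def __init__(self, genes: Iterable[GeneRecord], genome: str = "genome"):
        self.genome = genome
        self._by_id: dict[str, GeneRecord] = {}
        by_chrom: dict[str, list[GeneRecord]] = {}
        for g in genes:
            if g.gene_id in self._by_id:
                raise ValueError(f"duplicate gene_id {g.gene_id!r}")
            self._by_id[g.gene_id] = g
            by_chrom.setdefault(g.chromosome, []).append(g)
        self._by_chrom: dict[str, list[GeneRecord]] = {}
        for chrom, recs in by_chrom.items():
            recs.sort(key=lambda g: (g.start_bp, g.gene_id))
            fixed = []
            for i, g in enumerate(recs):
                if g.order_index != i:
                    g = GeneRecord(g.gene_id, g.chromosome, i, g.start_bp, g.end_bp, g.strand)
                    self._by_id[g.gene_id] = g
                fixed.append(g)
            self._by_chrom[chrom] = fixed

    @classmethod
    def from_positions(
        cls,
        rows: Iterable[tuple[str, str, int, int, str]],
        genome: str = "genome",
    ) -> "ChromosomeMap":
        """Build from (gene_id, chromosome, start, end, strand) tuples."""
        return cls(
            (GeneRecord(gid, chrom, 0, s, e, strand) for gid, chrom, s, e, strand in rows),
            genome=genome,
        )

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def __len__(self) -> int:
        return len(self._by_id)

    def __iter__(self) -> Iterator[GeneRecord]:
        for chrom in sorted(self._by_chrom):
            yield from self._by_chrom[chrom]

    def __getitem__(self, gene_id: str) -> GeneRecord:
        try:
            return self._by_id[gene_id]
        except KeyError:
            raise KeyError(f"unknown gene_id {gene_id!r} in genome {self.genome!r}") from None

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._by_chrom)

    def genes_on(self, chromosome: str) -> list[GeneRecord]:
        return list(self._by_chrom[chromosome])

    def chromosome_length(self, chromosome: str) -> int:
        """End of the last gene — a lower bound used when no length table is given."""
        return max(g.end_bp for g in self._by_chrom[chromosome])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (g.gene_id, g.chromosome, g.order_index, g.start_bp, g.end_bp, g.strand)
                for g in self
            ],
            columns=["gene_id", "chromosome", "order_index", "start_bp", "end_bp", "strand"],
        )


def read_gff3(path: str | Path, genome: str = "genome", feature: str = "gene") -> ChromosomeMap:
    """Read gene features from GFF3 (1-based closed; converted on read)."""
    df = pr.read_gff3(str(path)).df
    df = df[df["Feature"] == feature]
    if "ID" not in df.columns:
        raise ValueError(f"{path}: GFF3 gene features carry no ID attribute")
    rows = [
        (str(r.ID), str(r.Chromosome), int(r.Start), int(r.End), str(r.Strand))
        for r in df.itertuples()
    ]
    return ChromosomeMap.from_positions(rows, genome=genome)


def read_bed(path: str | Path, genome: str = "genome") -> ChromosomeMap:
    """Read BED6 gene records (already 0-based half-open)."""
    df = pr.read_bed(str(path)).df
    rows = [
        (str(r.Name), str(r.Chromosome), int(r.Start), int(r.End), str(r.Strand))
        for r in df.itertuples()
    ]
    return ChromosomeMap.from_positions(rows, genome=genome)


def read_gene_map(path: str | Path, genome: str = "genome") -> ChromosomeMap:
    p = str(path)
    if p.endswith((".bed", ".bed6")):
        return read_bed(p, genome=genome)
    return read_gff3(p, genome=genome)


@dataclass(frozen=True)
class HomologyHit:
    """One protein search hit; only ids, e-value and bit score are used."""

    query_id: str
    subject_id: str
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"hit {self.query_id}-{self.subject_id}: negative e-value")

    @property
    def is_self(self) -> bool:
        return self.query_id == self.subject_id


HIT_COLUMNS = [
    "query", "subject", "identity", "length", "mismatches", "gapopens",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_hits(path: str | Path) -> list[HomologyHit]:
    """Read a 12-column tabular hit file; columns 1, 2, 11, 12 are consumed."""
    df = pd.read_csv(path, sep="\t", header=None, names=HIT_COLUMNS, comment="#")
    return [
        HomologyHit(str(r.query), str(r.subject), float(r.evalue), float(r.bitscore))
        for r in df.itertuples()
    ]


def write_hits(hits: Iterable[HomologyHit], path: str | Path) -> None:
    """Write hits in the 12-column layout; unused columns are zero-filled."""
    rows = []
    for h in hits:
        rows.append([h.query_id, h.subject_id, 0.0, 0, 0, 0, 0, 0, 0, 0, h.evalue, h.bitscore])
    pd.DataFrame(rows, columns=HIT_COLUMNS).to_csv(path, sep="\t", header=False, index=False)
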