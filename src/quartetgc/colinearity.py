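"""Colinear (synteny) block detection and Ks-based block dating.

Homology hits are filtered on e-value/bit-score and gene-family size, chained
into runs of gene pairs whose order is preserved on both chromosomes (allowing
inversions), and each block is dated to a duplication or speciation event by
the median synonymous divergence of its anchor pairs.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .genome import ChromosomeMap, HomologyHit

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class BlockParams:
    """Thresholds for hit filtering and chaining.

    Defaults follow common whole-genome colinearity practice: hits kept at
    e-value < 1e-5 and score > 100, a maximum chaining gap of 50 intervening
    genes, blocks of at least four anchors, and removal of gene families with
    50 or more members.
    """

    max_gap: int = 50
    min_anchors: int = 4
    max_family_size: int = 50
    evalue_max: float = 1e-5
    bitscore_min: float = 100.0

    def __post_init__(self) -> None:
        if self.max_gap < 0 or self.min_anchors < 2:
            raise ValueError("max_gap must be >= 0 and min_anchors >= 2")
        if self.max_family_size <= 0 or self.evalue_max <= 0:
            raise ValueError("max_family_size and evalue_max must be positive")


@dataclass
class ColinearBlock:
    """A chained run of homologous gene pairs between two chromosomal regions."""

    block_id: str
    genome_a: str
    genome_b: str
    chrom_a: str
    chrom_b: str
    orientation: str  # "parallel" | "inverted"
    anchors: list[tuple[str, str]]
    score: float = 0.0  # sum of -log10 e-values; reported, never used to filter
    median_ks: float | None = None
    event: str = "unassigned"

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)


class KsEventWindows:
    """Named, disjoint Ks intervals mapping a block's median Ks to an event."""

    def __init__(self, windows: Sequence[tuple[str, float, float, bool]]):
        self.windows = list(windows)
        for name, lo, hi, _ in self.windows:
            if lo < 0 or hi < lo:
                raise ValueError(f"window {name}: bad bounds [{lo}, {hi}]")
        spans = sorted((lo, hi) for _, lo, hi, _ in self.windows)
        for (l1, h1), (l2, h2) in zip(spans, spans[1:]):
            if l2 < h1:
                raise ValueError("Ks event windows overlap")

    @classmethod
    def default(cls) -> "KsEventWindows":
        # Recent-divergence window [0, 0.35) vs old-duplication window [0.5, 1.2]
        # on the JC-corrected Ps scale.
        # The bounds are a config-level choice the user should review per dataset.
        return cls([
            ("PRT_or_speciation", 0.0, 0.35, False),
            ("LCT", 0.5, 1.2, True),
        ])

    def classify(self, ks: float) -> str:
        for name, lo, hi, hi_inclusive in self.windows:
            if lo <= ks < hi or (hi_inclusive and ks == hi):
                return name
        return "other"


def filter_hits(
    hits: Iterable[HomologyHit],
    params: BlockParams,
    known_genes: set[str] | None = None,
) -> list[HomologyHit]:
    """Apply e-value/bit-score thresholds, drop self-hits and large families.

    Family size is the gene's number of distinct partners in the
    post-threshold hit graph; every hit touching a gene with
    ``max_family_size`` or more partners is removed.
    """
    kept = []
    for h in hits:
        if known_genes is not None:
            for gid in (h.query_id, h.subject_id):
                if gid not in known_genes:
                    raise KeyError(f"hit references unknown gene_id {gid!r}")
        if h.is_self:
            continue
        if h.evalue < params.evalue_max and h.bitscore > params.bitscore_min:
            kept.append(h)

    partners: dict[str, set[str]] = {}
    for h in kept:
        partners.setdefault(h.query_id, set()).add(h.subject_id)
        partners.setdefault(h.subject_id, set()).add(h.query_id)
    big = {g for g, p in partners.items() if len(p) >= params.max_family_size}
    if big:
        log.info("family filter removed %d genes with >= %d partners", len(big), params.max_family_size)
    return [h for h in kept if h.query_id not in big and h.subject_id not in big]


def remove_large_families_from_blocks(
    blocks: Sequence[ColinearBlock],
    hits: Iterable[HomologyHit],
    params: BlockParams,
) -> list[ColinearBlock]:
    """Post-chaining variant of the gene-family filter.

    Drops anchors whose genes have ``max_family_size`` or more distinct
    partners in the (threshold-filtered) hit graph, then discards blocks
    that fall below ``min_anchors``.  Alternative to applying the family
    filter before chaining (``filter_hits``).
    """
    partners: dict[str, set[str]] = {}
    for h in hits:
        if h.is_self:
            continue
        if h.evalue < params.evalue_max and h.bitscore > params.bitscore_min:
            partners.setdefault(h.query_id, set()).add(h.subject_id)
            partners.setdefault(h.subject_id, set()).add(h.query_id)
    big = {g for g, p in partners.items() if len(p) >= params.max_family_size}
    out = []
    for b in blocks:
        anchors = [(ga, gb) for ga, gb in b.anchors if ga not in big and gb not in big]
        if len(anchors) >= params.min_anchors:
            out.append(replace(b, anchors=anchors))
    return out


# ---------------------------------------------------------------------------
# chaining


def _chain_key(points, id_of_a, id_of_b):
    """Deterministic, genome-symmetric comparison key for equal-score chains."""
    return tuple(tuple(sorted((id_of_a[a], id_of_b[b]))) for a, b in points)


def _best_chain(
    points: list[tuple[int, int]],
    max_gap: int,
    id_of_a: Mapping[int, str],
    id_of_b: Mapping[int, str],
) -> list[tuple[int, int]] | None:
    """Highest-scoring monotone gap-constrained chain among ``points``.

    Score order: more anchors, then smaller total gap, then the
    lexicographically smallest chain of sorted gene-id pairs (symmetric under
    swapping the two genomes), then parallel before inverted.
    """
    best = None  # (count_neg, gap, key, orient_rank, chain)
    for orient_rank, sign in ((0, 1), (1, -1)):
        pts = sorted(points, key=lambda p: (p[0], sign * p[1]))
        n = len(pts)
        # dp[i]: best (count, gap, key-chain) for a chain ending at pts[i]
        dp: list[tuple[int, int, list[tuple[int, int]]]] = [None] * n  # type: ignore
        for i in range(n):
            ai, bi = pts[i]
            cand = (1, 0, [pts[i]])
            for j in range(i):
                aj, bj = pts[j]
                if aj >= ai:
                    continue
                if sign * (bi - bj) <= 0:
                    continue
                if (ai - aj - 1) > max_gap or (abs(bi - bj) - 1) > max_gap:
                    continue
                cj, gj, chj = dp[j]
                ext = (cj + 1, gj + (ai - aj - 1) + (abs(bi - bj) - 1), chj + [pts[i]])
                if (-ext[0], ext[1], _chain_key(ext[2], id_of_a, id_of_b)) < (
                    -cand[0], cand[1], _chain_key(cand[2], id_of_a, id_of_b)
                ):
                    cand = ext
            dp[i] = cand
            entry = (
                -cand[0], cand[1], _chain_key(cand[2], id_of_a, id_of_b),
                orient_rank, cand[2],
            )
            if best is None or entry[:4] < best[:4]:
                best = entry
    return None if best is None else best[4]


def chain_anchors(
    points: list[tuple[int, int]],
    max_gap: int,
    min_anchors: int,
    id_of_a: Mapping[int, str],
    id_of_b: Mapping[int, str],
) -> list[list[tuple[int, int]]]:
    """Greedy best-chain extraction: accept the top chain, remove its points,
    re-chain the remainder until no chain reaches ``min_anchors``."""
    remaining = list(dict.fromkeys(points))
    chains = []
    while len(remaining) >= min_anchors:
        chain = _best_chain(remaining, max_gap, id_of_a, id_of_b)
        if chain is None or len(chain) < min_anchors:
            break
        chains.append(chain)
        used = set(chain)
        remaining = [p for p in remaining if p not in used]
    return chains


def _orientation(chain: list[tuple[int, int]]) -> str:
    if len(chain) < 2 or chain[1][1] > chain[0][1]:
        return "parallel"
    return "inverted"


def detect_blocks(
    genes_a: ChromosomeMap,
    genes_b: ChromosomeMap,
    hits: Iterable[HomologyHit],
    params: BlockParams,
) -> list[ColinearBlock]:
    """Chain filtered hits into colinear blocks per chromosome pair.

    Hits may name their genes in either order; each is mapped onto
    (gene-in-A, gene-in-B).  When ``genes_a`` and ``genes_b`` are the same
    genome, unordered chromosome pairs are processed once and mirrored hits
    collapse onto one anchor.
    """
    same_genome = genes_a is genes_b or (
        genes_a.genome == genes_b.genome and len(genes_a) == len(genes_b)
    )
    # group unique anchors by chromosome pair
    by_pair: dict[tuple[str, str], dict[tuple[int, int], float]] = {}
    for h in hits:
        if h.is_self:
            continue
        q_in_a, s_in_a = h.query_id in genes_a, h.subject_id in genes_a
        q_in_b, s_in_b = h.query_id in genes_b, h.subject_id in genes_b
        if q_in_a and s_in_b:
            ga, gb = genes_a[h.query_id], genes_b[h.subject_id]
        elif s_in_a and q_in_b:
            ga, gb = genes_a[h.subject_id], genes_b[h.query_id]
        else:
            missing = h.query_id if not (q_in_a or q_in_b) else h.subject_id
            raise KeyError(f"hit references gene {missing!r} absent from both gene maps")
        ca, cb = ga.chromosome, gb.chromosome
        ia, ib = ga.order_index, gb.order_index
        if same_genome and (cb, ib) < (ca, ia):
            ca, cb, ia, ib = cb, ca, ib, ia
        key = (ca, cb)
        neglog = 300.0 if h.evalue == 0 else -math.log10(h.evalue)
        prev = by_pair.setdefault(key, {}).get((ia, ib))
        if prev is None or neglog > prev:
            by_pair[key][(ia, ib)] = neglog

    blocks: list[ColinearBlock] = []
    for (ca, cb) in sorted(by_pair):
        anchors_scores = by_pair[(ca, cb)]
        id_of_a = {g.order_index: g.gene_id for g in genes_a.genes_on(ca)}
        id_of_b = {g.order_index: g.gene_id for g in genes_b.genes_on(cb)}
        pts = sorted(anchors_scores)
        for chain in chain_anchors(pts, params.max_gap, params.min_anchors, id_of_a, id_of_b):
            bid = f"{genes_a.genome}_{ca}__{genes_b.genome}_{cb}__{len(blocks)}"
            blocks.append(
                ColinearBlock(
                    block_id=bid,
                    genome_a=genes_a.genome,
                    genome_b=genes_b.genome,
                    chrom_a=ca,
                    chrom_b=cb,
                    orientation=_orientation(chain),
                    anchors=[(id_of_a[ia], id_of_b[ib]) for ia, ib in chain],
                    score=sum(anchors_scores[p] for p in chain),
                )
            )
    return blocks


# ---------------------------------------------------------------------------
# dating


def _lower_median(values: Sequence[float]) -> float:
    """Median taking the lower of the two middle values at even counts."""
    s = sorted(values)
    return s[(len(s) - 1) // 2]


def date_block(
    block: ColinearBlock,
    pair_ks: Mapping[tuple[str, str], float],
    windows: KsEventWindows,
    min_ks_fraction: float = 0.5,
) -> ColinearBlock:
    """Label a block by the Ks window containing its anchors' median Ks."""
    ks = []
    for a, b in block.anchors:
        v = pair_ks.get((a, b), pair_ks.get((b, a)))
        if v is not None and v == v:  # drop NaN (saturated pairs)
            ks.append(v)
    if not ks or len(ks) < min_ks_fraction * block.n_anchors:
        log.warning("block %s: Ks available for %d/%d anchors; left unassigned",
                    block.block_id, len(ks), block.n_anchors)
        return replace(block, median_ks=None, event="unassigned")
    med = _lower_median(ks)
    return replace(block, median_ks=med, event=windows.classify(med))


def date_blocks(blocks, pair_ks, windows, min_ks_fraction: float = 0.5):
    return [date_block(b, pair_ks, windows, min_ks_fraction) for b in blocks]


# ---------------------------------------------------------------------------
# TSV round-trip

BLOCK_COLUMNS = ["block_id", "genome_a", "genome_b", "chrom_a", "chrom_b",
                 "orientation", "n_anchors", "score", "median_ks", "event"]


def blocks_to_frames(blocks: Sequence[ColinearBlock]) -> tuple[pd.DataFrame, pd.DataFrame]:
    brows, arows = [], []
    for b in blocks:
        brows.append([b.block_id, b.genome_a, b.genome_b, b.chrom_a, b.chrom_b,
                      b.orientation, b.n_anchors, b.score,
                      "" if b.median_ks is None else b.median_ks, b.event])
        for i, (ga, gb) in enumerate(b.anchors):
            arows.append([b.block_id, i, ga, gb])
    return (
        pd.DataFrame(brows, columns=BLOCK_COLUMNS),
        pd.DataFrame(arows, columns=["block_id", "anchor_index", "gene_a", "gene_b"]),
    )


def write_blocks(blocks: Sequence[ColinearBlock], blocks_path, anchors_path) -> None:
    bdf, adf = blocks_to_frames(blocks)
    bdf.to_csv(blocks_path, sep="\t", index=False)
    adf.to_csv(anchors_path, sep="\t", index=False)


def read_blocks(blocks_path, anchors_path) -> list[ColinearBlock]:
    bdf = pd.read_csv(blocks_path, sep="\t", dtype={"median_ks": float})
    adf = pd.read_csv(anchors_path, sep="\t")
    anchors_by_block: dict[str, list[tuple[str, str]]] = {}
    for r in adf.sort_values(["block_id", "anchor_index"]).itertuples():
        anchors_by_block.setdefault(r.block_id, []).append((r.gene_a, r.gene_b))
    out = []
    for r in bdf.itertuples():
        mks = None if pd.isna(r.median_ks) else float(r.median_ks)
        out.append(ColinearBlock(
            block_id=r.block_id, genome_a=r.genome_a, genome_b=r.genome_b,
            chrom_a=str(r.chrom_a), chrom_b=str(r.chrom_b), orientation=r.orientation,
            anchors=anchors_by_block.get(r.block_id, []), score=float(r.score),
            median_ks=mks, event=r.event,
        ))
    return out
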