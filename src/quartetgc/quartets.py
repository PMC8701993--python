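"""Homologous gene quartets: assembly from dated blocks, alignment, filtering.

A quartet couples one duplicated (paralogous) gene pair with the two genes'
respective orthologs in another genome or subgenome.  Two role layouts are
supported: the within-genome duplication pattern (A1, A2 paralogs in genome A
with orthologs B1, B2 in genome B) and the allotetraploid pattern (Ama, Amb
homoeologs in the two subgenomes with orthologs Ad, Ai in the two parental
diploids).  Internally roles are always ordered (p1, p2, o1, o2) where o1 is
the ortholog of p1 and o2 of p2.
"""
from __future__ import annotations

import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .colinearity import ColinearBlock
from .rates import GAP, CodonAlignment, back_translate, translate_cds

ROLE_NAMES = {
    "LCT": ("A1", "A2", "B1", "B2"),
    "PRT": ("Ama", "Amb", "Ad", "Ai"),
}


@dataclass
class Quartet:
    quartet_id: str
    pattern: str  # "LCT" | "PRT"
    genes: tuple[str, str, str, str]  # (p1, p2, o1, o2)
    block_ids: dict = field(default_factory=dict)
    alignment: CodonAlignment | None = None
    protein_alignment: tuple[str, ...] | None = None
    filter_status: str = "kept"

    @property
    def roles(self) -> dict[str, str]:
        return dict(zip(ROLE_NAMES[self.pattern], self.genes))


@dataclass(frozen=True)
class QuartetFilterParams:
    """Alignment-quality thresholds below which a quartet is discarded.

    ``pair_scope`` chooses which induced pairs are tested: all six, or only
    the paralog pair plus the two role-matched ortholog pairs.
    """

    max_gap_fraction: float = 0.50
    min_identity: float = 0.40
    pair_scope: str = "all"  # "all" | "role_matched"

    def __post_init__(self) -> None:
        if not (0 < self.max_gap_fraction <= 1 and 0 < self.min_identity <= 1):
            raise ValueError("thresholds must lie in (0, 1]")
        if self.pair_scope not in ("all", "role_matched"):
            raise ValueError("pair_scope must be 'all' or 'role_matched'")


ALL_PAIRS = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
ROLE_MATCHED_PAIRS = [(0, 1), (0, 2), (1, 3)]


# ---------------------------------------------------------------------------
# assembly


def paralog_pairs_from_blocks(
    blocks: Iterable[ColinearBlock], event: str
) -> list[tuple[str, str, str]]:
    """(gene1, gene2, block_id) anchors of blocks dated to ``event``."""
    out = []
    for b in blocks:
        if b.event == event:
            out.extend((ga, gb, b.block_id) for ga, gb in b.anchors)
    return out


def ortholog_map_from_blocks(
    blocks: Iterable[ColinearBlock], event: str, reverse: bool = False
) -> dict[str, list[tuple[str, int, str]]]:
    """gene -> [(ortholog, block anchor count, block_id)] from event-dated blocks."""
    out: dict[str, list[tuple[str, int, str]]] = {}
    for b in blocks:
        if b.event != event:
            continue
        for ga, gb in b.anchors:
            if reverse:
                ga, gb = gb, ga
            out.setdefault(ga, []).append((gb, b.n_anchors, b.block_id))
    return out


def build_quartets(
    paralog_pairs: Sequence[tuple[str, str, str]],
    ortholog_map_1: Mapping[str, list[tuple[str, int, str]]],
    ortholog_map_2: Mapping[str, list[tuple[str, int, str]]],
    pattern: str = "LCT",
) -> tuple[list[Quartet], int]:
    """One quartet per paralog pair whose both members have colinear orthologs.

    Ortholog ambiguity is resolved toward the highest-anchor-count block
    (ties toward the lexicographically first ortholog id).  Pairs whose two
    members resolve to the same ortholog are rejected and counted; the count
    is returned alongside the quartets.
    """
    if pattern not in ROLE_NAMES:
        raise ValueError(f"unknown quartet pattern {pattern!r}")
    quartets: list[Quartet] = []
    n_same_ortholog = 0

    def best(cands):
        return min(cands, key=lambda c: (-c[1], c[0]))

    for p1, p2, block_id in paralog_pairs:
        c1 = ortholog_map_1.get(p1)
        c2 = ortholog_map_2.get(p2)
        if not c1 or not c2:
            continue
        o1, _, b1 = best(c1)
        o2, _, b2 = best(c2)
        if o1 == o2:
            n_same_ortholog += 1
            continue
        qid = f"{pattern}_{len(quartets):05d}_{p1}_{p2}"
        quartets.append(
            Quartet(
                quartet_id=qid,
                pattern=pattern,
                genes=(p1, p2, o1, o2),
                block_ids={"paralog": block_id, "ortholog_1": b1, "ortholog_2": b2},
            )
        )
    return quartets, n_same_ortholog


# ---------------------------------------------------------------------------
# alignment


def mafft_align(ids: Sequence[str], seqs: Sequence[str]) -> list[str]:
    """Multiple protein alignment via the mafft command line (deterministic)."""
    with tempfile.NamedTemporaryFile("w", suffix=".fa", delete=False) as fh:
        for sid, s in zip(ids, seqs):
            fh.write(f">{sid}\n{s}\n")
        path = fh.name
    try:
        res = subprocess.run(
            ["mafft", "--quiet", "--retree", "2", "--maxiterate", "0", path],
            capture_output=True, text=True, check=True,
        )
    finally:
        Path(path).unlink(missing_ok=True)
    by_id = {}
    for rec in SeqIO.parse(_string_handle(res.stdout), "fasta"):
        by_id[rec.id] = str(rec.seq).upper()
    return [by_id[sid] for sid in ids]


def _string_handle(text: str):
    import io

    return io.StringIO(text)


def attach_alignment(
    q: Quartet,
    cds_by_id: Mapping[str, str],
    table: str = "Standard",
) -> Quartet:
    """Align the quartet's four proteins (mafft) and back-translate to codons."""
    cds = [cds_by_id[g].upper() for g in q.genes]
    prots = [translate_cds(c, table) for c in cds]
    aligned = mafft_align(q.genes, prots)
    q.protein_alignment = tuple(aligned)
    q.alignment = CodonAlignment(
        tuple(q.genes),
        tuple(back_translate(a, c) for a, c in zip(aligned, cds)),
        source="back_translated",
        metadata={"aligner": "mafft --retree 2 --maxiterate 0"},
    )
    return q


def quartet_from_aligned(
    qid: str, pattern: str, genes: Sequence[str], aligned_cds: Sequence[str],
    table: str = "Standard",
) -> Quartet:
    """Build a quartet from already-aligned CDS (e.g. indel-free simulations)."""
    aln = CodonAlignment(tuple(genes), tuple(s.upper() for s in aligned_cds), source="given")
    # translate codon-wise, keeping gap triplets as protein gaps
    from .rates import _code

    code = _code(table)
    prots = []
    for s in aln.aligned_cds:
        aas = []
        for i in range(0, len(s), 3):
            cod = s[i:i + 3]
            aas.append(GAP if GAP in cod else code.get(cod, "X"))
        if aas and aas[-1] == "*":
            aas[-1] = GAP
        prots.append("".join(aas))
    return Quartet(
        quartet_id=qid, pattern=pattern, genes=tuple(genes),
        alignment=aln, protein_alignment=tuple(prots),
    )


# ---------------------------------------------------------------------------
# filtering


def pairwise_alignment_stats(pa: str, pb: str) -> tuple[float, float]:
    """(gap_fraction, identity) of one induced pair of aligned proteins.

    Columns gapped in both sequences are not part of the induced pairwise
    alignment.  Gap fraction uses the full induced length; identity uses
    only columns where both sequences have residues.
    """
    length = gaps = shared = match = 0
    for x, y in zip(pa, pb):
        if x == GAP and y == GAP:
            continue
        length += 1
        if x == GAP or y == GAP:
            gaps += 1
        else:
            shared += 1
            if x == y:
                match += 1
    if length == 0:
        return 1.0, 0.0
    identity = match / shared if shared else 0.0
    return gaps / length, identity


def filter_quartets(
    quartets: Iterable[Quartet], params: QuartetFilterParams = QuartetFilterParams()
) -> dict[str, list[Quartet]]:
    """Partition quartets into kept / removed_gap / removed_identity."""
    pairs = ALL_PAIRS if params.pair_scope == "all" else ROLE_MATCHED_PAIRS
    out: dict[str, list[Quartet]] = {"kept": [], "removed_gap": [], "removed_identity": []}
    for q in quartets:
        if q.protein_alignment is None:
            raise ValueError(f"quartet {q.quartet_id}: protein alignment not attached")
        stats = [pairwise_alignment_stats(q.protein_alignment[i], q.protein_alignment[j])
                 for i, j in pairs]
        if any(gf > params.max_gap_fraction for gf, _ in stats):
            q.filter_status = "removed_gap"
        elif any(ident < params.min_identity for _, ident in stats):
            q.filter_status = "removed_identity"
        else:
            q.filter_status = "kept"
        out[q.filter_status].append(q)
    return out


# ---------------------------------------------------------------------------
# TSV / FASTA round-trip

QUARTET_COLUMNS = ["quartet_id", "pattern", "p1", "p2", "o1", "o2",
                   "paralog_block", "ortholog_block_1", "ortholog_block_2", "filter_status"]


def write_quartets(quartets: Sequence[Quartet], tsv_path, aln_dir=None) -> None:
    rows = []
    for q in quartets:
        rows.append([q.quartet_id, q.pattern, *q.genes,
                     q.block_ids.get("paralog", ""), q.block_ids.get("ortholog_1", ""),
                     q.block_ids.get("ortholog_2", ""), q.filter_status])
        if aln_dir is not None and q.alignment is not None:
            d = Path(aln_dir)
            d.mkdir(parents=True, exist_ok=True)
            with open(d / f"{q.quartet_id}.aln.fa", "w") as fh:
                for sid, s in zip(q.alignment.seq_ids, q.alignment.aligned_cds):
                    fh.write(f">{sid}\n{s}\n")
    pd.DataFrame(rows, columns=QUARTET_COLUMNS).to_csv(tsv_path, sep="\t", index=False)


def read_quartets(tsv_path, aln_dir=None, table: str = "Standard") -> list[Quartet]:
    df = pd.read_csv(tsv_path, sep="\t", keep_default_na=False)
    out = []
    for r in df.itertuples():
        genes = (r.p1, r.p2, r.o1, r.o2)
        q = Quartet(
            quartet_id=r.quartet_id, pattern=r.pattern, genes=genes,
            block_ids={k: v for k, v in (("paralog", r.paralog_block),
                                         ("ortholog_1", r.ortholog_block_1),
                                         ("ortholog_2", r.ortholog_block_2)) if v},
            filter_status=r.filter_status,
        )
        if aln_dir is not None:
            path = Path(aln_dir) / f"{q.quartet_id}.aln.fa"
            if path.exists():
                recs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
                q2 = quartet_from_aligned(q.quartet_id, q.pattern, genes,
                                          [recs[g] for g in genes], table)
                q.alignment, q.protein_alignment = q2.alignment, q2.protein_alignment
        out.append(q)
    return out
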