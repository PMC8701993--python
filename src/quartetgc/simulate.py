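"""Synthetic quartets and toy genome sets with planted gene conversions.

Sequences evolve under a Jukes–Cantor nucleotide process along the quartet
tree ((p1,o1),(p2,o2)): an old duplication at depth ``t_duplication`` and a
recent divergence at ``t_speciation`` (depths in expected substitutions per
site per lineage).  Substitutions that would create a stop codon are
redirected to a non-stop base; nonsynonymous changes are accepted with
probability ``omega`` (purifying selection).  A planted conversion
instantaneously overwrites the acceptor paralog — wholly or over a window —
with the donor's current sequence at a chosen time after the divergence; the
donor is never altered.  Every planted event is recorded in a truth table so
each pipeline stage can be scored against known history.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import ChromosomeMap, GeneRecord, HomologyHit, write_hits
from .rates import _code

BASES = "ACGT"
_CODE = _code("Standard")
SENSE_CODONS = sorted(c for c, aa in _CODE.items() if aa != "*")


@dataclass
class SimConfig:
    """Study conditions for the generator; defaults are the package's
    reference simulation regime (see docs/methods.md for the rationale)."""

    rng_seed: int = 0
    n_genes_per_chromosome: int = 100
    n_chromosomes: int = 1
    gene_length_codons: tuple[int, int] = (300, 600)
    substitution_rate: float = 1.0  # per site per unit time
    t_duplication: float = 0.4  # per-lineage depth, expected subs/site
    t_speciation: float = 0.1
    conversion_fraction: float = 0.2
    conversion_kind_mix: dict = field(default_factory=lambda: {"whole": 0.8, "partial": 0.2})
    partial_len_nt: tuple[int, int] = (30, 300)
    conversion_time: float = 0.75  # fraction of t_speciation elapsed before overwrite
    # omega = 1 is the default pure-JC nucleotide process; set omega < 1
    # (optionally with a relaxed post-duplication omega_predup) to switch on
    # the codon model with purifying selection
    omega: float = 1.0
    omega_predup: float | None = None
    hit_fpr: float = 0.02
    gene_family_inflation: int = 0  # number of families inflated past the filter
    inversion_rate: float = 0.0  # expected inversions per duplicated chromosome
    gene_loss_rate: float = 0.0
    pattern: str = "LCT"

    def __post_init__(self) -> None:
        if self.t_duplication <= self.t_speciation or self.t_speciation <= 0:
            raise ValueError("need t_duplication > t_speciation > 0")
        for frac in (self.conversion_fraction, self.conversion_time, self.omega,
                     self.hit_fpr, self.gene_loss_rate):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        if self.substitution_rate < 0 or self.inversion_rate < 0:
            raise ValueError("rates must be non-negative")
        expected_p = 0.75 * (1 - np.exp(-(8.0 / 3.0) * self.substitution_rate * self.t_duplication))
        if expected_p >= 0.7:
            import logging

            logging.getLogger(__name__).warning(
                "deep-pair expected p-distance %.2f approaches saturation", expected_p)


@dataclass
class SimTruth:
    """Ground truth for one quartet."""

    quartet_id: str
    genes: tuple[str, str, str, str]  # (p1, p2, o1, o2)
    converted: bool
    kind: str  # "whole" | "partial" | "none"
    donor_role: str = ""
    acceptor_role: str = ""
    segment: tuple[int, int] | None = None  # nt on the acceptor CDS, 0-based half-open
    divergences: dict = field(default_factory=dict)  # realized pairwise p-distances


def random_cds(n_codons: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(SENSE_CODONS, size=n_codons))


def evolve(seq: str, depth: float, rng: np.random.Generator,
           rate: float = 1.0, omega: float = 1.0) -> str:
    """Evolve a CDS for ``depth`` time units of Jukes–Cantor substitution.

    Substitution attempts arrive as a Poisson process at ``rate`` per site;
    a hit picks one of the three alternative bases uniformly.  Hits creating
    a stop codon are redirected uniformly to a non-stop alternative;
    amino-acid-changing hits are accepted with probability ``omega``.
    """
    s = list(seq)
    L = len(s)
    n = rng.poisson(rate * depth * L)
    if n == 0:
        return seq
    sites = rng.integers(0, L, size=n)
    choices = rng.integers(0, 3, size=n)
    redirect_draws = rng.random(size=n)
    accept_draws = rng.random(size=n)
    for site, choice, rdraw, draw in zip(sites, choices, redirect_draws, accept_draws):
        old = s[site]
        alts = [b for b in BASES if b != old]
        new = alts[choice]
        cstart = (site // 3) * 3
        codon = s[cstart:cstart + 3]
        pos = site - cstart
        old_aa = _CODE["".join(codon)]

        def aa_with(b):
            c = codon.copy()
            c[pos] = b
            return _CODE["".join(c)]

        if aa_with(new) == "*":
            ok = [b for b in alts if aa_with(b) != "*"]
            if not ok:
                continue
            new = ok[int(rdraw * len(ok)) % len(ok)]
        new_aa = aa_with(new)
        if new_aa != old_aa and omega < 1.0 and draw >= omega:
            continue
        s[site] = new
    return "".join(s)


def p_distance(a: str, b: str) -> float:
    arr_a = np.frombuffer(a.encode(), dtype="S1")
    arr_b = np.frombuffer(b.encode(), dtype="S1")
    return float(np.mean(arr_a != arr_b))


def _choose_kind(cfg: SimConfig, rng: np.random.Generator) -> str:
    kinds = sorted(cfg.conversion_kind_mix)
    probs = np.array([cfg.conversion_kind_mix[k] for k in kinds], dtype=float)
    probs = probs / probs.sum()
    return kinds[rng.choice(len(kinds), p=probs)]


def simulate_quartet(
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    quartet_id: str = "q0",
    gene_ids: Sequence[str] | None = None,
) -> tuple[dict[str, str], SimTruth]:
    """One quartet of CDS plus its ground truth.

    Returns ``(sequences, truth)`` where sequences maps role keys
    p1/p2/o1/o2 to ungapped CDS strings of equal length (no indels are
    simulated, so the sequences are mutually aligned as emitted).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed)
    mu = cfg.substitution_rate
    n_cod = int(rng.integers(cfg.gene_length_codons[0], cfg.gene_length_codons[1] + 1))
    anc = random_cds(n_cod, rng)
    pre = cfg.t_duplication - cfg.t_speciation
    omega_pre = cfg.omega if cfg.omega_predup is None else cfg.omega_predup
    lin1 = evolve(anc, pre, rng, mu, omega_pre)
    lin2 = evolve(anc, pre, rng, mu, omega_pre)

    converted = bool(rng.random() < cfg.conversion_fraction)
    kind = _choose_kind(cfg, rng) if converted else "none"
    donor_first = bool(rng.random() < 0.5)

    t1 = cfg.conversion_time * cfg.t_speciation
    t2 = cfg.t_speciation - t1
    # phase 1: duplication lineages split into (paralog, ortholog) copies
    p1 = evolve(lin1, t1, rng, mu, cfg.omega)
    p2 = evolve(lin2, t1, rng, mu, cfg.omega)
    o1 = evolve(lin1, t1, rng, mu, cfg.omega)
    o2 = evolve(lin2, t1, rng, mu, cfg.omega)

    segment = None
    donor_role = acceptor_role = ""
    if converted:
        donor_role, acceptor_role = ("p1", "p2") if donor_first else ("p2", "p1")
        donor_seq = p1 if donor_first else p2
        if kind == "whole":
            new_acc = donor_seq
        else:
            lo, hi = cfg.partial_len_nt
            # snapped to codon boundaries so chimeric codons cannot be stops
            length = 3 * int(rng.integers(max(1, lo // 3), hi // 3 + 1))
            length = min(length, 3 * n_cod)
            start = 3 * int(rng.integers(0, n_cod - length // 3 + 1))
            segment = (start, start + length)
            acc_seq = p2 if donor_first else p1
            new_acc = acc_seq[:start] + donor_seq[start:start + length] + acc_seq[start + length:]
        if donor_first:
            p2 = new_acc
        else:
            p1 = new_acc
    # phase 2: evolve everything to the present
    p1 = evolve(p1, t2, rng, mu, cfg.omega)
    p2 = evolve(p2, t2, rng, mu, cfg.omega)
    o1 = evolve(o1, t2, rng, mu, cfg.omega)
    o2 = evolve(o2, t2, rng, mu, cfg.omega)

    seqs = {"p1": p1, "p2": p2, "o1": o1, "o2": o2}
    ids = tuple(gene_ids) if gene_ids else (f"{quartet_id}_p1", f"{quartet_id}_p2",
                                            f"{quartet_id}_o1", f"{quartet_id}_o2")
    div = {f"{x}-{y}": p_distance(seqs[x], seqs[y])
           for x, y in (("p1", "p2"), ("p1", "o1"), ("p2", "o2"),
                        ("p1", "o2"), ("p2", "o1"), ("o1", "o2"))}
    truth = SimTruth(
        quartet_id=quartet_id, genes=ids, converted=converted, kind=kind,
        donor_role=donor_role, acceptor_role=acceptor_role, segment=segment,
        divergences=div,
    )
    return seqs, truth


# ---------------------------------------------------------------------------
# genome-set simulation


@dataclass
class SimulatedGenomeSet:
    cds: dict[str, str]
    gene_maps: dict[str, ChromosomeMap]
    hits: list[HomologyHit]
    truth: list[SimTruth]
    annotation: pd.DataFrame

    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.truth:
            seg = t.segment or ("", "")
            rows.append([t.quartet_id, *t.genes, t.converted, t.kind,
                         t.donor_role, t.acceptor_role, seg[0], seg[1]])
        return pd.DataFrame(rows, columns=[
            "quartet_id", "p1", "p2", "o1", "o2", "converted", "kind",
            "donor_role", "acceptor_role", "segment_start", "segment_end"])

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write FASTA / GFF3 / hit TSV / truth TSV / annotation TSV."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for genome, gmap in self.gene_maps.items():
            fa = out / f"{genome}.cds.fa"
            with open(fa, "w") as fh:
                for g in gmap:
                    fh.write(f">{g.gene_id}\n{self.cds[g.gene_id]}\n")
            gff = out / f"{genome}.genes.gff3"
            with open(gff, "w") as fh:
                fh.write("##gff-version 3\n")
                for g in gmap:
                    fh.write(
                        f"{g.chromosome}\tquartetgc_sim\tgene\t{g.start_bp + 1}\t{g.end_bp}"
                        f"\t.\t{g.strand}\t.\tID={g.gene_id}\n")
            paths[f"{genome}.cds"] = fa
            paths[f"{genome}.genes"] = gff
        paths["hits"] = out / "hits.tsv"
        write_hits(self.hits, paths["hits"])
        paths["truth"] = out / "truth.tsv"
        self.truth_frame().to_csv(paths["truth"], sep="\t", index=False)
        paths["annotation"] = out / "annotation.tsv"
        self.annotation.to_csv(paths["annotation"], sep="\t", index=False)
        return paths


def _hit_from_identity(qid: str, sid: str, L_nt: int, p: float) -> HomologyHit:
    """Deterministic plausible e-value/bit score from simulated identity."""
    bitscore = max(55.0, 2.0 * (L_nt / 3) * (1.0 - p))
    evalue = 10.0 ** (-min(180.0, bitscore / 3.0))
    return HomologyHit(qid, sid, evalue, bitscore)


def simulate_genome_set(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> SimulatedGenomeSet:
    """Two genomes descended from one duplicated ancestor, with planted truth.

    Each ancestral chromosome ``cK`` yields duplicated chromosomes ``cKa`` /
    ``cKb`` in both genomes G1 and G2; gene order is colinear up to planted
    inversions and losses.  Conversions are planted between the two G1
    copies (the within-genome paralog pair), so G1 is the focal genome and
    G2 supplies the orthologs.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed)
    genes: dict[str, str] = {}
    records: dict[str, list[tuple[str, str, int]]] = {"G1": [], "G2": []}  # (id, chrom, len_nt)
    truths: list[SimTruth] = []
    for ci in range(cfg.n_chromosomes):
        for j in range(cfg.n_genes_per_chromosome):
            qid = f"c{ci + 1}_{j:04d}"
            ids = (f"G1_c{ci + 1}a_{j:04d}", f"G1_c{ci + 1}b_{j:04d}",
                   f"G2_c{ci + 1}a_{j:04d}", f"G2_c{ci + 1}b_{j:04d}")
            seqs, truth = simulate_quartet(cfg, rng, quartet_id=qid, gene_ids=ids)
            genes[ids[0]], genes[ids[1]] = seqs["p1"], seqs["p2"]
            genes[ids[2]], genes[ids[3]] = seqs["o1"], seqs["o2"]
            L = len(seqs["p1"])
            records["G1"].append((ids[0], f"c{ci + 1}a", L))
            records["G1"].append((ids[1], f"c{ci + 1}b", L))
            records["G2"].append((ids[2], f"c{ci + 1}a", L))
            records["G2"].append((ids[3], f"c{ci + 1}b", L))
            truths.append(truth)

    # gene losses
    if cfg.gene_loss_rate > 0:
        lost = {gid for gid in sorted(genes) if rng.random() < cfg.gene_loss_rate}
        genes = {g: s for g, s in genes.items() if g not in lost}
        records = {gn: [r for r in rs if r[0] not in lost] for gn, rs in records.items()}

    # planted inversions: reverse a span of gene order on the "b" copies
    order: dict[tuple[str, str], list[tuple[str, int]]] = {}
    for gn, rs in records.items():
        for gid, chrom, L in rs:
            order.setdefault((gn, chrom), []).append((gid, L))
    for (gn, chrom), lst in sorted(order.items()):
        if not chrom.endswith("b"):
            continue
        n_inv = rng.poisson(cfg.inversion_rate)
        for _ in range(n_inv):
            if len(lst) < 4:
                break
            span = int(rng.integers(3, max(4, len(lst) // 4)))
            start = int(rng.integers(0, len(lst) - span + 1))
            lst[start:start + span] = lst[start:start + span][::-1]

    # lay out coordinates
    gene_maps = {}
    for gn in ("G1", "G2"):
        rows = []
        for chrom in sorted({c for (g, c) in order if g == gn}):
            pos = int(rng.integers(2000, 10000))
            for gid, L in order[(gn, chrom)]:
                rows.append((gid, chrom, pos, pos + L, "+"))
                pos += L + int(rng.integers(2000, 10000))
        gene_maps[gn] = ChromosomeMap.from_positions(rows, genome=gn)

    # homology hits among surviving copies of each quartet
    hits: list[HomologyHit] = []
    for t in truths:
        present = [g for g in t.genes if g in genes]
        for i in range(len(present)):
            for j in range(i + 1, len(present)):
                a, b = present[i], present[j]
                p = p_distance(genes[a], genes[b])
                hits.append(_hit_from_identity(a, b, len(genes[a]), p))
    n_true = len(hits)

    # spurious hits that pass the thresholds but cannot chain
    all_ids = sorted(genes)
    n_fp = int(round(cfg.hit_fpr * n_true))
    for _ in range(n_fp):
        a, b = rng.choice(len(all_ids), size=2, replace=False)
        bitscore = float(rng.uniform(105, 160))
        hits.append(HomologyHit(all_ids[a], all_ids[b], 10.0 ** float(rng.uniform(-40, -6)),
                                bitscore))

    # inflate selected gene families past the family-size filter
    for k in range(cfg.gene_family_inflation):
        hub = all_ids[int(rng.integers(0, len(all_ids)))]
        partners = rng.choice(len(all_ids), size=55, replace=False)
        for idx in partners:
            if all_ids[idx] != hub:
                hits.append(HomologyHit(hub, all_ids[idx], 1e-30, 200.0))

    # annotation with one category enriched among converted genes
    ann_rows = []
    categories = [f"CAT{k:03d}" for k in range(10)]
    conv_genes = {g for t in truths if t.converted for g in t.genes[:2]}
    for gid in all_ids:
        for cat in categories:
            base = 0.08
            if cat == "CAT000" and gid in conv_genes:
                base = 0.6
            if rng.random() < base:
                ann_rows.append((gid, cat, "simulated"))
    annotation = pd.DataFrame(ann_rows, columns=["gene_id", "category_id", "namespace"])
    return SimulatedGenomeSet(genes, gene_maps, hits, truths, annotation)
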