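"""Nei–Gojobori (1986) synonymous/nonsynonymous distances with Jukes–Cantor correction.

For each ungapped codon column the number of synonymous sites is the fraction
of the three possible single-nucleotide changes at each position that preserve
the amino acid (changes to stop codons are never counted as synonymous).
Differences between two codons are resolved by averaging synonymous and
nonsynonymous steps over all minimal single-substitution pathways; pathways
passing through a stop codon are skipped unless every pathway does, in which
case all are re-admitted.  Raw proportions Ks = Sd/S and Ka = Nd/N are
corrected for multiple hits with the one-parameter Jukes–Cantor formula,
giving the corrected values Ps and Pn.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data import CodonTable
from Bio.Seq import Seq

GAP = "-"
BASES = "ACGT"


@lru_cache(maxsize=None)
def _code(table: str = "Standard") -> dict[str, str]:
    """codon -> amino acid, '*' for stop."""
    tab = CodonTable.unambiguous_dna_by_name[table]
    code = dict(tab.forward_table)
    for stop in tab.stop_codons:
        code[stop] = "*"
    return code


def translate_cds(cds: str, table: str = "Standard") -> str:
    """Translate a CDS, stripping one terminal stop; error on internal stops."""
    cds = cds.upper()
    if len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
    code = _code(table)
    aas = []
    for i in range(0, len(cds), 3):
        aa = code.get(cds[i:i + 3])
        if aa is None:
            raise ValueError(f"unrecognized codon {cds[i:i+3]!r} at position {i}")
        aas.append(aa)
    if aas and aas[-1] == "*":
        aas.pop()
    if "*" in aas:
        raise ValueError(f"internal stop codon at codon {aas.index('*')}")
    return "".join(aas)


@lru_cache(maxsize=None)
def syn_sites(codon: str, table: str = "Standard") -> float:
    """NG86 synonymous site count of one codon (0..3)."""
    code = _code(table)
    aa = code[codon]
    if aa == "*":
        raise ValueError(f"stop codon {codon!r} has no site decomposition")
    s = 0.0
    for pos in range(3):
        syn = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if code[alt] != "*" and code[alt] == aa:
                syn += 1
        s += syn / 3.0
    return s


@lru_cache(maxsize=None)
def pathway_counts(c1: str, c2: str, table: str = "Standard") -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) differences between codons."""
    code = _code(table)
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return (0.0, 0.0)

    def walk(order):
        cur, sd, nd, ok = c1, 0.0, 0.0, True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if code[nxt] == "*":
                ok = False
            if code[nxt] == code[cur] and code[nxt] != "*" and code[cur] != "*":
                sd += 1
            else:
                nd += 1
            cur = nxt
        return sd, nd, ok

    results = [walk(order) for order in itertools.permutations(diff)]
    admissible = [(sd, nd) for sd, nd, ok in results if ok]
    if not admissible:  # all pathways hit a stop: re-admit them all
        admissible = [(sd, nd) for sd, nd, _ in results]
    sd = sum(x for x, _ in admissible) / len(admissible)
    nd = sum(x for _, x in admissible) / len(admissible)
    return (sd, nd)


def jc_correct(p: float) -> float:
    """Jukes–Cantor multiple-hit correction −(3/4)·ln(1 − 4p/3).

    Returns NaN at or beyond the saturation boundary p >= 0.75.
    """
    if p < 0:
        raise ValueError("proportion must be non-negative")
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log1p(-(4.0 / 3.0) * p)


@dataclass(frozen=True)
class CodonAlignment:
    """An aligned set of CDS sequences (equal length, multiple of 3)."""

    seq_ids: tuple[str, ...]
    aligned_cds: tuple[str, ...]
    source: str = "given"  # "given" | "back_translated"
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        lens = {len(s) for s in self.aligned_cds}
        if len(lens) != 1:
            raise ValueError("aligned sequences differ in length")
        (n,) = lens
        if n % 3:
            raise ValueError("alignment length is not a multiple of 3")
        for sid, s in zip(self.seq_ids, self.aligned_cds):
            bad = set(s.upper()) - set(BASES + GAP)
            if bad:
                raise ValueError(f"{sid}: unexpected symbols {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.aligned_cds[0])

    @property
    def n_codons(self) -> int:
        return len(self) // 3

    def codons(self, index: int) -> list[str]:
        s = self.aligned_cds[index].upper()
        return [s[i:i + 3] for i in range(0, len(s), 3)]

    def pair(self, i: int, j: int) -> "CodonAlignment":
        return CodonAlignment(
            (self.seq_ids[i], self.seq_ids[j]),
            (self.aligned_cds[i], self.aligned_cds[j]),
            source=self.source,
        )


@dataclass
class PairRates:
    """NG86 site counts, difference counts and (corrected) distances for one pair."""

    gene_a: str
    gene_b: str
    s_sites: float
    n_sites: float
    sd: float
    nd: float
    ks_raw: float
    ka_raw: float
    ps: float
    pn: float
    pn_ps: float
    flags: list[str] = field(default_factory=list)


def ng86_profile(codons_a: list[str], codons_b: list[str], table: str = "Standard") -> np.ndarray:
    """Per-codon-column NG86 contributions, shape (n_codons, 5).

    Columns are (sd, nd, s_a, s_b, compared); gapped/ambiguous/stop columns
    contribute all-zero rows (pairwise deletion).
    """
    out = np.zeros((len(codons_a), 5))
    code = _code(table)
    for k, (ca, cb) in enumerate(zip(codons_a, codons_b)):
        if GAP in ca or GAP in cb:
            continue
        if set(ca) - set(BASES) or set(cb) - set(BASES):
            continue
        if code[ca] == "*" or code[cb] == "*":
            continue
        sd, nd = pathway_counts(ca, cb, table)
        out[k] = (sd, nd, syn_sites(ca, table), syn_sites(cb, table), 1.0)
    return out


def ng86_from_profile(profile: np.ndarray, gene_a: str = "a", gene_b: str = "b") -> PairRates:
    sd, nd, sa, sb, used = profile.sum(axis=0)
    s_sites = (sa + sb) / 2.0
    n_sites = 3.0 * used - s_sites
    flags: list[str] = []
    if used == 0:
        raise ValueError("no ungapped codon column shared by the pair")
    if s_sites == 0:
        flags.append("no_synonymous_sites")
        ks_raw = math.nan
    else:
        ks_raw = sd / s_sites
    ka_raw = nd / n_sites if n_sites > 0 else math.nan
    ps = jc_correct(ks_raw) if ks_raw == ks_raw else math.nan
    pn = jc_correct(ka_raw) if ka_raw == ka_raw else math.nan
    if ks_raw == ks_raw and ks_raw >= 0.75:
        flags.append("ks_saturated")
    if ka_raw == ka_raw and ka_raw >= 0.75:
        flags.append("ka_saturated")
    pn_ps = pn / ps if ps == ps and ps > 0 and pn == pn else math.nan
    if ps == 0:
        flags.append("pn_ps_undefined")
    return PairRates(gene_a, gene_b, s_sites, n_sites, sd, nd, ks_raw, ka_raw, ps, pn, pn_ps, flags)


def ng86(aln: CodonAlignment, table: str = "Standard") -> PairRates:
    """NG86 distances for a two-sequence codon alignment."""
    if len(aln.seq_ids) != 2:
        raise ValueError("ng86 operates on exactly two sequences")
    profile = ng86_profile(aln.codons(0), aln.codons(1), table)
    return ng86_from_profile(profile, aln.seq_ids[0], aln.seq_ids[1])


# ---------------------------------------------------------------------------
# alignment

_ALIGNER_PARAMS = {"matrix": "BLOSUM62", "open_gap_score": -10.0, "extend_gap_score": -0.5}


def _protein_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(_ALIGNER_PARAMS["matrix"])
    aligner.open_gap_score = _ALIGNER_PARAMS["open_gap_score"]
    aligner.extend_gap_score = _ALIGNER_PARAMS["extend_gap_score"]
    return aligner


def back_translate(aligned_prot: str, cds: str) -> str:
    """Expand an aligned protein back to codons of its source CDS."""
    out, i = [], 0
    for aa in aligned_prot:
        if aa == GAP:
            out.append(GAP * 3)
        else:
            out.append(cds[i:i + 3])
            i += 3
    if i not in (len(cds), len(cds) - 3):  # terminal stop may remain untranslated
        raise ValueError("protein alignment does not cover the CDS")
    return "".join(out)


def align_pair(
    cds_a: str,
    cds_b: str,
    prot_a: str | None = None,
    prot_b: str | None = None,
    ids: tuple[str, str] = ("a", "b"),
    table: str = "Standard",
) -> CodonAlignment:
    """Globally align a coding pair at the protein level, back-translated to codons."""
    ta, tb = translate_cds(cds_a, table), translate_cds(cds_b, table)
    for name, given, trans in ((ids[0], prot_a, ta), (ids[1], prot_b, tb)):
        if given is not None and given.rstrip("*") != trans:
            raise ValueError(f"{name}: CDS does not translate to the supplied protein")
    aligner = _protein_aligner()
    alignment = aligner.align(ta, tb)[0]
    pa, pb = str(alignment[0]), str(alignment[1])
    return CodonAlignment(
        tuple(ids),
        (back_translate(pa, cds_a.upper()), back_translate(pb, cds_b.upper())),
        source="back_translated",
        metadata={"aligner": "Bio.Align.PairwiseAligner/global", **_ALIGNER_PARAMS},
    )
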