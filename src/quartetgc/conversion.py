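"""Gene-conversion detectors on homologous quartets.

In a quartet (p1, p2 paralogs; o1, o2 their orthologs) the orthologous pairs
diverged after the paralogous pairs, so without conversion the gene tree
groups each paralog with its ortholog.  Conversion overwrites one paralog
with the other and pulls the paralog pair together, flipping the quartet
topology.  Three detectors are provided:

* WCV-I  — topology on raw synonymous (NG86 Ks) distances, assessed by a
  codon-column bootstrap.
* WCV-II — amino-acid identity dominance of the paralog pair plus a
  topology flip on amino-acid p-distances (deterministic, more stringent).
* PCV    — a max-subarray scan for converted sub-gene segments longer than
  10 nt, with a column-permutation significance test.

Topology is decided by the four-point condition: for four taxa the pairing
with the minimal distance sum names the unrooted tree, which coincides with
neighbor-joining on additive distances and is exactly bootstrappable.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .quartets import ALL_PAIRS, Quartet
from .rates import GAP, ng86_from_profile, ng86_profile

EXPECTED = "expected"
PARALOG_GROUPING = "paralog_grouping"
OTHER = "other"


@dataclass(frozen=True)
class DetectorParams:
    bootstrap_reps: int = 1000
    wcv1_support_min: float = 0.95
    pcv_min_len_nt: int = 11
    pcv_min_support_sites: int = 3
    pcv_opposing_penalty: float = 2.0
    pcv_max_support_spacing: int = 9
    pcv_perm_reps: int = 1000
    pcv_alpha: float = 0.05
    rng_seed: int = 0
    suppress_pcv_on_wcv: bool = True

    def __post_init__(self) -> None:
        if not (0.5 < self.wcv1_support_min <= 1):
            raise ValueError("wcv1_support_min must lie in (0.5, 1]")
        if min(self.bootstrap_reps, self.pcv_min_len_nt, self.pcv_min_support_sites,
               self.pcv_perm_reps) <= 0 or self.pcv_opposing_penalty <= 0:
            raise ValueError("detector parameters must be positive")


@dataclass
class ConversionCall:
    quartet_id: str
    detector: str  # "WCV-I" | "WCV-II" | "PCV"
    converted_side: str = "first_genome"
    support: float = 1.0
    donor_role: str = "ambiguous"
    acceptor_role: str = "ambiguous"
    segment: tuple[int, int] | None = None  # nt on the alignment, 0-based half-open

    @property
    def segment_len_nt(self) -> int:
        return 0 if self.segment is None else self.segment[1] - self.segment[0]


def quartet_topology(
    d_p1p2: float, d_o1o2: float, d_p1o1: float, d_p2o2: float,
    d_p1o2: float, d_p2o1: float,
) -> str:
    """Four-point topology of the quartet from its six pairwise distances.

    Exact ties involving the expected (orthologous) pairing resolve to
    ``expected`` — the conservative, no-conversion reading.
    """
    for d in (d_p1p2, d_o1o2, d_p1o1, d_p2o2, d_p1o2, d_p2o1):
        if not math.isfinite(d):
            raise ValueError("all six distances must be finite")
    s_orth = d_p1o1 + d_p2o2
    s_par = d_p1p2 + d_o1o2
    s_cross = d_p1o2 + d_p2o1
    if s_orth <= s_par and s_orth <= s_cross:
        return EXPECTED
    if s_par < s_cross:
        return PARALOG_GROUPING
    if s_cross < s_par:
        return OTHER
    return EXPECTED


# ---------------------------------------------------------------------------
# WCV-I: synonymous-distance topology with codon bootstrap


def _pair_profiles(q: Quartet, table: str = "Standard") -> np.ndarray:
    """NG86 per-codon contributions for all 6 pairs, shape (n_codons, 6, 5)."""
    codons = [q.alignment.codons(i) for i in range(4)]
    return np.stack(
        [ng86_profile(codons[i], codons[j], table) for i, j in ALL_PAIRS], axis=1
    )


def _ks_from_sums(t: np.ndarray) -> np.ndarray:
    """Raw Ks per pair from summed profiles t[..., (sd, nd, sa, sb, used)]."""
    s = (t[..., 2] + t[..., 3]) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(s > 0, t[..., 0] / s, np.nan)


def _topology_codes(ks: np.ndarray) -> np.ndarray:
    """Vectorized four-point calls; ks has shape (..., 6) ordered as ALL_PAIRS."""
    s_par = ks[..., 0] + ks[..., 5]  # d(p1,p2) + d(o1,o2)
    s_orth = ks[..., 1] + ks[..., 4]  # d(p1,o1) + d(p2,o2)
    s_cross = ks[..., 2] + ks[..., 3]  # d(p1,o2) + d(p2,o1)
    par = (s_par < s_orth) & (s_par < s_cross)
    ok = np.isfinite(s_par) & np.isfinite(s_orth) & np.isfinite(s_cross)
    return par & ok


def detect_wcv1(
    q: Quartet, params: DetectorParams = DetectorParams(),
    rng: np.random.Generator | None = None, table: str = "Standard",
) -> ConversionCall | None:
    """Whole-gene conversion by synonymous-distance topology + codon bootstrap."""
    if rng is None:
        rng = np.random.default_rng(params.rng_seed)
    prof = _pair_profiles(q, table)  # (ncod, 6, 5)
    totals = prof.sum(axis=0)  # (6, 5)
    ks = _ks_from_sums(totals)
    if not np.all(np.isfinite(ks)):
        return None  # saturated / empty pair: no call, caller counts it
    topo = quartet_topology(ks[0], ks[5], ks[1], ks[4], ks[2], ks[3])
    if topo != PARALOG_GROUPING:
        return None
    ncod = prof.shape[0]
    w = rng.multinomial(ncod, np.full(ncod, 1.0 / ncod), size=params.bootstrap_reps)
    rep_tot = np.tensordot(w.astype(float), prof.reshape(ncod, -1), axes=1)
    rep_tot = rep_tot.reshape(params.bootstrap_reps, 6, 5)
    rep_ks = _ks_from_sums(rep_tot)
    support = float(np.mean(_topology_codes(rep_ks)))
    if support < params.wcv1_support_min:
        return None
    side = "first_genome" if ks[0] < ks[5] else ("second_genome" if ks[5] < ks[0] else "both")
    return ConversionCall(q.quartet_id, "WCV-I", converted_side=side, support=support)


# ---------------------------------------------------------------------------
# WCV-II: amino-acid identity dominance + aa-distance topology


def _aa_identity(pa: str, pb: str) -> float | None:
    shared = match = 0
    for x, y in zip(pa, pb):
        if x == GAP or y == GAP:
            continue
        shared += 1
        if x == y:
            match += 1
    return None if shared == 0 else match / shared


def detect_wcv2(
    q: Quartet, params: DetectorParams = DetectorParams()
) -> ConversionCall | None:
    """Whole-gene conversion by amino-acid identity; deterministic and stricter.

    The paralog pair must be strictly more similar than BOTH role-matched
    ortholog pairs, and the quartet topology on amino-acid p-distances must
    group the paralogs.
    """
    prots = q.protein_alignment
    idents = {}
    for i, j in ALL_PAIRS:
        v = _aa_identity(prots[i], prots[j])
        if v is None:
            return None
        idents[(i, j)] = v
    id_par, id_o1, id_o2 = idents[(0, 1)], idents[(0, 2)], idents[(1, 3)]
    if not (id_par > id_o1 and id_par > id_o2):
        return None
    d = {k: 1.0 - v for k, v in idents.items()}
    topo = quartet_topology(d[(0, 1)], d[(2, 3)], d[(0, 2)], d[(1, 3)], d[(0, 3)], d[(1, 2)])
    if topo != PARALOG_GROUPING:
        return None
    side = ("first_genome" if d[(0, 1)] < d[(2, 3)]
            else "second_genome" if d[(2, 3)] < d[(0, 1)] else "both")
    return ConversionCall(q.quartet_id, "WCV-II", converted_side=side, support=1.0)


# ---------------------------------------------------------------------------
# PCV: partial-conversion segment scan


def classify_columns(q: Quartet) -> np.ndarray:
    """Score each nucleotide column: +1 supporting, -penalty-marker -1 opposing, 0 neutral.

    Supporting: the paralogs share a state that breaks the orthologous
    grouping (p1 == p2 while p1 != o1 or p2 != o2).  Opposing: each paralog
    matches its own ortholog and the paralogs differ.  Gapped columns are
    neutral.  The returned array holds +1 / -1 / 0; the caller applies the
    opposing penalty weight.
    """
    a = np.array([list(s.upper()) for s in q.alignment.aligned_cds])
    p1, p2, o1, o2 = a[0], a[1], a[2], a[3]
    no_gap = ~np.any(a == GAP, axis=0)
    supporting = no_gap & (p1 == p2) & ((p1 != o1) | (p2 != o2))
    opposing = no_gap & (p1 == o1) & (p2 == o2) & (p1 != p2)
    out = np.zeros(a.shape[1], dtype=np.int8)
    out[supporting] = 1
    out[opposing] = -1
    return out


def _max_subarray(scores: np.ndarray) -> tuple[int, int, float]:
    """Best-sum contiguous segment (start, end, sum), trimmed to scoring ends."""
    best_sum, best = -math.inf, (0, 0)
    run_sum, run_start = 0.0, 0
    for i, x in enumerate(scores):
        if run_sum <= 0:
            run_sum, run_start = x, i
        else:
            run_sum += x
        if run_sum > best_sum:
            best_sum, best = run_sum, (run_start, i + 1)
    s, e = best
    while s < e and scores[s] <= 0:
        s += 1
    while e > s and scores[e - 1] <= 0:
        e -= 1
    return s, e, float(scores[s:e].sum())


def _max_subarray_sums(mat: np.ndarray) -> np.ndarray:
    """Row-wise maximal subarray sums (vectorized Kadane across rows)."""
    run = np.zeros(mat.shape[0])
    best = np.full(mat.shape[0], -np.inf)
    for j in range(mat.shape[1]):
        run = np.maximum(run, 0.0) + mat[:, j]
        best = np.maximum(best, run)
    return best


def detect_pcv(
    q: Quartet, params: DetectorParams = DetectorParams(),
    rng: np.random.Generator | None = None,
) -> list[ConversionCall]:
    """Partial-gene conversion segments (> 10 nt) by scored max-subarray scan.

    Column scores are shuffled ``pcv_perm_reps`` times and the maximal
    segment score recomputed to obtain a permutation p-value per segment.
    """
    if rng is None:
        rng = np.random.default_rng(params.rng_seed)
    L = len(q.alignment)
    if L < params.pcv_min_len_nt:
        return []
    labels = classify_columns(q)
    scores = np.where(labels > 0, 1.0, np.where(labels < 0, -params.pcv_opposing_penalty, 0.0))
    a = np.array([list(s.upper()) for s in q.alignment.aligned_cds])
    paralog_diff = (a[0] != a[1]) & (a[0] != GAP) & (a[1] != GAP)
    # column classes for boundary refinement:
    # 0 neutral, 1 supporting, 2 opposing, 3 paralog mismatch (non-opposing)
    cls = np.zeros(L, dtype=int)
    cls[labels > 0] = 1
    cls[labels < 0] = 2
    cls[paralog_diff & (labels == 0)] = 3

    # permutation null of the maximal segment score, shared by all segments
    perm = np.tile(scores, (params.pcv_perm_reps, 1))
    perm = rng.permuted(perm, axis=1)
    null_max = _max_subarray_sums(perm)

    calls: list[ConversionCall] = []

    def refine(s: int, e: int, lo: int, hi: int) -> tuple[int, int] | None:
        """Changepoint refinement of a candidate tract [s, e).

        Column-class frequencies inside the core vs outside it give
        log-likelihood-ratio weights; each boundary is moved to the position
        maximizing the inside-likelihood of the retained columns, then
        extended to the midpoint of the uninformative gap before the first
        contradicting (paralog-mismatch) column outside.
        """
        inside = np.bincount(cls[s:e], minlength=4) + 0.5
        outside = np.concatenate([cls[:s], cls[e:]])
        out_counts = np.bincount(outside, minlength=4) + 0.5
        w = np.log((inside / inside.sum()) / (out_counts / out_counts.sum()))
        wv = w[cls]
        mid = (s + e) // 2
        # left boundary: maximize the summed weight of columns [b, mid)
        b_lo = max(lo, s - 40)
        if mid > b_lo:
            suffix = np.cumsum(wv[b_lo:mid][::-1])[::-1]
            rs = b_lo + int(np.argmax(suffix))
        else:
            rs = s
        # right boundary: maximize over (mid, b]
        b_hi = min(hi, e + 40)
        if b_hi > mid:
            prefix = np.cumsum(wv[mid:b_hi])
            re_ = mid + int(np.argmax(prefix)) + 1
        else:
            re_ = e
        sup = np.flatnonzero(labels[rs:re_] > 0) + rs
        if len(sup) == 0:
            return None
        rs, re_ = int(sup[0]), int(sup[-1]) + 1
        # the tract edge lies between the outermost supporting site and the
        # nearest paralog-mismatch site beyond it; take the gap midpoint
        j = rs - 1
        while j >= lo and not paralog_diff[j]:
            j -= 1
        rs = (j + 1 + rs) // 2
        j = re_
        while j < hi and not paralog_diff[j]:
            j += 1
        re_ = (re_ + j + 1) // 2
        return rs, re_

    def scan(lo: int, hi: int) -> None:
        if hi - lo < 1:
            return
        s, e, seg_sum = _max_subarray(scores[lo:hi])
        if seg_sum <= 0:
            return
        s, e = lo + s, lo + e
        bounds = refine(s, e, lo, hi)
        if bounds is not None:
            rs, re_ = bounds
            n_support = int(np.sum(labels[rs:re_] > 0))
            seg_score = float(scores[rs:re_].sum())
            if (re_ - rs >= params.pcv_min_len_nt
                    and n_support >= params.pcv_min_support_sites):
                p = (1.0 + np.sum(null_max >= seg_score)) / (1.0 + params.pcv_perm_reps)
                if p < params.pcv_alpha:
                    calls.append(ConversionCall(
                        q.quartet_id, "PCV", support=1.0 - p, segment=(rs, re_),
                    ))
        scan(lo, s)
        scan(e, hi)

    scan(0, L)
    calls.sort(key=lambda c: c.segment)
    return calls


# ---------------------------------------------------------------------------
# donor / acceptor assignment


def _p_distance(sa: str, sb: str, region: tuple[int, int] | None = None) -> float:
    if region is not None:
        sa, sb = sa[region[0]:region[1]], sb[region[0]:region[1]]
    shared = diff = 0
    for x, y in zip(sa.upper(), sb.upper()):
        if x == GAP or y == GAP:
            continue
        shared += 1
        if x != y:
            diff += 1
    return math.nan if shared == 0 else diff / shared


def assign_donor(call: ConversionCall, q: Quartet) -> ConversionCall:
    """Assign donor/acceptor via the diploid (outgroup) orthologs.

    In the allotetraploid pattern the acceptor is the copy that sits closer
    to the OTHER subgenome's diploid ortholog than to its own; the donor is
    the other copy.  Within-genome (LCT) quartets have no such outgroup and
    stay ambiguous.  Distances are nucleotide p-distances over the converted
    segment (PCV) or the whole alignment (WCV).
    """
    if q.pattern != "PRT":
        return replace(call, donor_role="ambiguous", acceptor_role="ambiguous")
    region = call.segment if call.detector == "PCV" else None
    p1, p2, o1, o2 = q.alignment.aligned_cds
    d_p1_own, d_p1_other = _p_distance(p1, o1, region), _p_distance(p1, o2, region)
    d_p2_own, d_p2_other = _p_distance(p2, o2, region), _p_distance(p2, o1, region)
    roles = list(q.roles)
    p1_acceptor = d_p1_other < d_p1_own
    p2_acceptor = d_p2_other < d_p2_own
    if p1_acceptor == p2_acceptor:  # neither or both: ambiguous (incl. ties)
        return replace(call, donor_role="ambiguous", acceptor_role="ambiguous")
    acc, don = (roles[0], roles[1]) if p1_acceptor else (roles[1], roles[0])
    return replace(call, donor_role=don, acceptor_role=acc)


# ---------------------------------------------------------------------------
# driver + summaries


@dataclass
class DetectionResult:
    calls: list[ConversionCall]
    n_skipped_saturated: int = 0


def detect_all(
    quartets: Iterable[Quartet], params: DetectorParams = DetectorParams(),
    seed: int | None = None, table: str = "Standard",
) -> DetectionResult:
    """Run WCV-I, WCV-II and (optionally suppressed) PCV over kept quartets."""
    rng = np.random.default_rng(params.rng_seed if seed is None else seed)
    calls: list[ConversionCall] = []
    n_sat = 0
    for q in quartets:
        if q.filter_status != "kept":
            continue
        try:
            c1 = detect_wcv1(q, params, rng, table)
        except ValueError:
            c1, _ = None, None
            n_sat += 1
        c2 = detect_wcv2(q, params)
        for c in (c1, c2):
            if c is not None:
                calls.append(assign_donor(c, q))
        if params.suppress_pcv_on_wcv and (c1 is not None or c2 is not None):
            continue
        calls.extend(assign_donor(c, q) for c in detect_pcv(q, params, rng))
    return DetectionResult(calls=calls, n_skipped_saturated=n_sat)


CALL_COLUMNS = ["quartet_id", "detector", "converted_side", "support",
                "donor_role", "acceptor_role", "segment_start", "segment_end", "segment_len_nt"]


def calls_to_frame(calls: Sequence[ConversionCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        seg = c.segment or ("", "")
        rows.append([c.quartet_id, c.detector, c.converted_side, c.support,
                     c.donor_role, c.acceptor_role, seg[0], seg[1], c.segment_len_nt])
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


def write_calls(calls: Sequence[ConversionCall], path) -> None:
    calls_to_frame(calls).to_csv(path, sep="\t", index=False)


def read_calls(path) -> list[ConversionCall]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    out = []
    for r in df.itertuples():
        seg = None
        if r.segment_start != "" and str(r.segment_start) != "nan":
            seg = (int(r.segment_start), int(r.segment_end))
        out.append(ConversionCall(
            quartet_id=r.quartet_id, detector=r.detector, converted_side=r.converted_side,
            support=float(r.support), donor_role=r.donor_role, acceptor_role=r.acceptor_role,
            segment=seg,
        ))
    return out


def summarize_calls(quartets: Sequence[Quartet], calls: Sequence[ConversionCall]) -> pd.DataFrame:
    """Per-detector counts and the union conversion rate over kept quartets.

    Quartets are counted once in the total even when flagged by several
    detectors; the per-detector columns report each detector separately.
    """
    kept = [q for q in quartets if q.filter_status == "kept"]
    by_det: dict[str, set[str]] = {"WCV-I": set(), "WCV-II": set(), "PCV": set()}
    for c in calls:
        by_det[c.detector].add(c.quartet_id)
    union = set().union(*by_det.values())
    n = len(kept)
    return pd.DataFrame([{
        "quartets_kept": n,
        "wcv1": len(by_det["WCV-I"]),
        "wcv2": len(by_det["WCV-II"]),
        "pcv": len(by_det["PCV"]),
        "total_converted": len(union),
        "conversion_rate_pct": 100.0 * len(union) / n if n else 0.0,
    }])
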