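"""Independent brute-force oracles used to validate the main implementations.

Everything here is written against the method definitions directly —
exhaustive enumeration, no shared code with the package internals beyond the
genetic code table.
"""
from __future__ import annotations

import itertools
import math

from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_name["Standard"]
CODE = dict(_TABLE.forward_table)
for _stop in _TABLE.stop_codons:
    CODE[_stop] = "*"
BASES = "ACGT"


def ng86_pair_oracle(seq_a: str, seq_b: str) -> tuple[float, float, float, float]:
    """(s_sites, n_sites, sd, nd) for two aligned CDS by explicit enumeration."""
    s_a = s_b = 0.0
    sd = nd = 0.0
    n_codons = 0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i:i + 3].upper(), seq_b[i:i + 3].upper()
        if "-" in ca or "-" in cb:
            continue
        if CODE.get(ca, "*") == "*" or CODE.get(cb, "*") == "*":
            continue
        n_codons += 1
        s_a += _syn_sites_oracle(ca)
        s_b += _syn_sites_oracle(cb)
        d_s, d_n = _pathway_oracle(ca, cb)
        sd += d_s
        nd += d_n
    s_sites = (s_a + s_b) / 2.0
    n_sites = 3.0 * n_codons - s_sites
    return s_sites, n_sites, sd, nd


def _syn_sites_oracle(codon: str) -> float:
    aa = CODE[codon]
    total = 0.0
    for pos in range(3):
        syn = sum(
            1
            for b in BASES
            if b != codon[pos]
            and CODE[codon[:pos] + b + codon[pos + 1:]] == aa
            and CODE[codon[:pos] + b + codon[pos + 1:]] != "*"
        )
        total += syn / 3.0
    return total


def _pathway_oracle(ca: str, cb: str) -> tuple[float, float]:
    diffs = [i for i in range(3) if ca[i] != cb[i]]
    if not diffs:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diffs):
        cur = ca
        steps = []
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
            if CODE[nxt] == "*":
                through_stop = True
            steps.append(CODE[nxt] != "*" and CODE[cur] != "*" and CODE[nxt] == CODE[cur])
            cur = nxt
        paths.append((through_stop, steps))
    usable = [steps for through, steps in paths if not through]
    if not usable:
        usable = [steps for _, steps in paths]
    sd = sum(sum(1 for s in steps if s) for steps in usable) / len(usable)
    nd = sum(sum(1 for s in steps if not s) for steps in usable) / len(usable)
    return sd, nd


# ---------------------------------------------------------------------------
# chain enumeration


def all_chains(points, max_gap, sign):
    """Every monotone gap-constrained chain (as tuples), one orientation."""
    pts = sorted(points, key=lambda p: (p[0], sign * p[1]))
    chains = []

    def extend(chain):
        chains.append(tuple(chain))
        last = chain[-1]
        for p in pts:
            if p[0] <= last[0]:
                continue
            if sign * (p[1] - last[1]) <= 0:
                continue
            if (p[0] - last[0] - 1) > max_gap or (abs(p[1] - last[1]) - 1) > max_gap:
                continue
            extend(chain + [p])

    for p in pts:
        extend([p])
    return chains


def _gap(chain):
    return sum((a2 - a1 - 1) + (abs(b2 - b1) - 1)
               for (a1, b1), (a2, b2) in zip(chain, chain[1:]))


def chain_oracle(points, max_gap, min_anchors, id_of_a, id_of_b):
    """Greedy best-chain extraction via exhaustive enumeration.

    Ordering: most anchors, smallest total gap, lexicographically smallest
    chain of sorted gene-id pairs, parallel before inverted — the deterministic
    tie policy the chaining module documents.
    """
    def key(chain, orient_rank):
        ids = tuple(tuple(sorted((id_of_a[a], id_of_b[b]))) for a, b in chain)
        return (-len(chain), _gap(chain), ids, orient_rank)

    remaining = list(dict.fromkeys(points))
    out = []
    while len(remaining) >= min_anchors:
        candidates = []
        for orient_rank, sign in ((0, 1), (1, -1)):
            candidates.extend((key(c, orient_rank), c) for c in all_chains(remaining, max_gap, sign))
        if not candidates:
            break
        best_key, best = min(candidates, key=lambda t: t[0])
        if len(best) < min_anchors:
            break
        out.append(list(best))
        used = set(best)
        remaining = [p for p in remaining if p not in used]
    return out


def topology_oracle(d_p1p2, d_o1o2, d_p1o1, d_p2o2, d_p1o2, d_p2o1):
    sums = {
        "expected": d_p1o1 + d_p2o2,
        "paralog_grouping": d_p1p2 + d_o1o2,
        "other": d_p1o2 + d_p2o1,
    }
    m = min(sums.values())
    winners = [k for k, v in sums.items() if v == m]
    if "expected" in winners or len(winners) > 1:
        return "expected"
    return winners[0]


def jc_oracle(p: float) -> float:
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)
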