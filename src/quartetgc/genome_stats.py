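"""Positional and functional statistics on conversion calls.

Covers terminal-distance binning of duplicated genes with a permutation test
of the fold increase near chromosome ends, a chi-square homogeneity test of
conversion rates across chromosomes, the association between block length and
conversion, and Pearson chi-square functional enrichment of converted genes.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .colinearity import ColinearBlock
from .genome import ChromosomeMap

log = logging.getLogger(__name__)


@dataclass
class BinSeries:
    """Per-bin duplicated/converted counts by distance from the arm terminus."""

    bin_width_bp: int
    duplicated: np.ndarray  # per-bin duplicated-gene counts
    converted: np.ndarray
    first_k_bins: int = 1
    approx_arms: bool = False
    fold_increase: float | None = None
    perm_p: float | None = None
    perm_rounds: int = 0

    @property
    def rates(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.duplicated > 0, self.converted / self.duplicated, np.nan)

    @property
    def occupied(self) -> np.ndarray:
        return self.duplicated > 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin": np.arange(len(self.duplicated)),
            "duplicated": self.duplicated,
            "converted": self.converted,
            "rate": self.rates,
        })


def bin_by_terminal_distance(
    genes: ChromosomeMap,
    duplicated: Iterable[str],
    converted: Iterable[str],
    chrom_lengths: Mapping[str, int] | None = None,
    arm_boundaries: Mapping[str, int] | None = None,
    bin_width_bp: int = 1_000_000,
    first_k_bins: int = 1,
) -> BinSeries:
    """Assign each duplicated gene to a distance bin from its arm terminus.

    Each chromosome has two arms meeting at the centromere
    (``arm_boundaries``); without a centromere table arms are approximated by
    the chromosome midpoint and the series flagged ``approx_arms``.  A gene's
    distance is measured from its gene start to the terminus of its arm, and
    bins are pooled across arms and chromosomes by index.
    """
    duplicated, converted = set(duplicated), set(converted)
    if not converted <= duplicated:
        raise ValueError("converted genes must be a subset of the duplicated set")
    lengths = dict(chrom_lengths or {})
    approx = arm_boundaries is None
    dup_bins, conv_bins = {}, {}
    for gid in sorted(duplicated):
        g = genes[gid]
        length = lengths.get(g.chromosome, genes.chromosome_length(g.chromosome))
        if g.start_bp > length:
            raise ValueError(f"gene {gid} lies beyond the length of {g.chromosome}")
        mid = (arm_boundaries or {}).get(g.chromosome, length // 2)
        pos = g.start_bp
        dist = pos if pos < mid else length - pos
        b = int(dist // bin_width_bp)
        dup_bins[b] = dup_bins.get(b, 0) + 1
        if gid in converted:
            conv_bins[b] = conv_bins.get(b, 0) + 1
    nbins = max(dup_bins, default=-1) + 1
    dup = np.zeros(nbins, dtype=int)
    conv = np.zeros(nbins, dtype=int)
    for b, c in dup_bins.items():
        dup[b] = c
    for b, c in conv_bins.items():
        conv[b] = c
    return BinSeries(bin_width_bp, dup, conv, first_k_bins=first_k_bins, approx_arms=approx)


def permutation_fold_test(
    series: BinSeries,
    rounds: int = 1_000_000,
    seed: int = 0,
) -> BinSeries:
    """Fold increase of the first bin(s) over the rest, with a permutation p.

    The observed fold is the mean rate of the first ``first_k_bins`` occupied
    bins divided by the mean rate of the remaining occupied bins.  Each round
    permutes the per-bin rates uniformly at random and recomputes the fold;
    the p-value uses the standard +1 correction so it can never be zero.
    """
    rates = series.rates[series.occupied]
    if len(rates) < 2:
        raise ValueError("need at least two occupied bins")
    k = series.first_k_bins
    obs_num, obs_den = rates[:k].mean(), rates[k:].mean()
    series.perm_rounds = rounds
    if obs_den == 0:
        series.fold_increase, series.perm_p = None, None
        log.warning("remaining-bin mean rate is 0; fold increase undefined")
        return series
    obs = obs_num / obs_den
    rng = np.random.default_rng(seed)
    perm = rng.permuted(np.tile(rates, (rounds, 1)), axis=1)
    num = perm[:, :k].mean(axis=1)
    den = perm[:, k:].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        folds = num / den
    exceed = int(np.sum(folds >= obs))
    series.fold_increase = float(obs)
    series.perm_p = (1.0 + exceed) / (1.0 + rounds)
    return series


def terminal_fraction_table(
    genes: ChromosomeMap,
    converted: Iterable[str],
    chrom_lengths: Mapping[str, int] | None = None,
    fractions: Sequence[float] = (0.1, 0.2, 0.3),
) -> pd.DataFrame:
    """Descriptive table: share of converted genes within terminal fractions."""
    converted = sorted(set(converted))
    lengths = dict(chrom_lengths or {})
    rows = []
    for frac in fractions:
        n_in = 0
        for gid in converted:
            g = genes[gid]
            length = lengths.get(g.chromosome, genes.chromosome_length(g.chromosome))
            dist = min(g.start_bp, length - g.start_bp)
            if dist <= frac * length / 2.0:
                n_in += 1
        rows.append({"terminal_fraction": frac, "converted_in": n_in,
                     "converted_total": len(converted),
                     "share": n_in / len(converted) if converted else 0.0})
    return pd.DataFrame(rows)


def chromosome_homogeneity(
    genes: ChromosomeMap,
    duplicated: Iterable[str],
    converted: Iterable[str],
) -> tuple[float, float, pd.DataFrame]:
    """Pearson chi-square for equal conversion rates across chromosomes."""
    duplicated, converted = set(duplicated), set(converted)
    per: dict[str, list[int]] = {}
    for gid in duplicated:
        chrom = genes[gid].chromosome
        row = per.setdefault(chrom, [0, 0])
        if gid in converted:
            row[0] += 1
        else:
            row[1] += 1
    per = {c: v for c, v in per.items() if sum(v) > 0}
    if len(per) < 2:
        raise ValueError("need at least two chromosomes with duplicated genes")
    table = np.array([per[c] for c in sorted(per)])
    if np.any(table.sum(axis=0) == 0):
        chi2, p = 0.0, 1.0
    else:
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    rates = pd.DataFrame({
        "chromosome": sorted(per),
        "converted": table[:, 0],
        "nonconverted": table[:, 1],
        "rate": table[:, 0] / table.sum(axis=1),
    })
    return float(chi2), float(p), rates


def block_length_association(
    blocks: Sequence[ColinearBlock],
    converted: Iterable[str],
    classes: Sequence[tuple[int, float]] = ((1, 10), (10, 50), (50, np.inf)),
) -> tuple[pd.DataFrame, float]:
    """Conversion rate by block-size class, plus per-block rate-vs-size r².

    A block's conversion rate is the share of its anchor pairs with at least
    one converted gene; classes stratify blocks by anchor count.
    """
    converted = set(converted)
    rows = []
    per_block = []
    for b in blocks:
        hit = sum(1 for ga, gb in b.anchors if ga in converted or gb in converted)
        rate = hit / b.n_anchors
        per_block.append((b.n_anchors, rate))
        rows.append({"block_id": b.block_id, "n_anchors": b.n_anchors,
                     "converted_anchors": hit, "rate": rate})
    per_block_df = pd.DataFrame(rows, columns=["block_id", "n_anchors",
                                               "converted_anchors", "rate"])
    class_rows = []
    for lo, hi in classes:
        sub = per_block_df[(per_block_df.n_anchors >= lo) & (per_block_df.n_anchors < hi)]
        class_rows.append({
            "class": f"[{lo},{'inf' if np.isinf(hi) else int(hi)})",
            "n_blocks": len(sub),
            "anchors": int(sub.n_anchors.sum()),
            "converted_anchors": int(sub.converted_anchors.sum()),
            "rate": sub.converted_anchors.sum() / sub.n_anchors.sum() if len(sub) else np.nan,
        })
    table = pd.DataFrame(class_rows)
    xs = np.array([n for n, _ in per_block])
    ys = np.array([r for _, r in per_block])
    if len(xs) > 1 and np.ptp(xs) > 0 and np.ptp(ys) > 0:
        r = stats.linregress(xs, ys).rvalue
        r2 = float(r * r)
    else:
        r2 = 0.0
    return table, r2


@dataclass
class EnrichmentRow:
    category_id: str
    converted_in: int
    converted_out: int
    nonconverted_in: int
    nonconverted_out: int
    chi2: float
    p: float
    p_bh: float = np.nan
    low_count: bool = False


def enrichment_chi2(
    annotation: Mapping[str, Sequence[str]] | pd.DataFrame,
    converted: Iterable[str],
    duplicated: Iterable[str],
    min_total: int = 5,
) -> list[EnrichmentRow]:
    """Per-category Pearson chi-square of converted vs nonconverted membership.

    ``annotation`` maps gene -> categories (many-to-many), either as a dict or
    a two-column DataFrame (gene_id, category_id).  Raw p-values are primary;
    a Benjamini–Hochberg column is emitted alongside.
    """
    converted, duplicated = set(converted), set(duplicated)
    missing = converted - duplicated
    if missing:
        raise ValueError(f"converted genes absent from duplicated set: {sorted(missing)[:5]}")
    if isinstance(annotation, pd.DataFrame):
        ann: dict[str, set[str]] = {}
        for r in annotation.itertuples():
            ann.setdefault(str(r.gene_id), set()).add(str(r.category_id))
    else:
        ann = {g: set(c) for g, c in annotation.items()}
    categories = sorted({c for g in duplicated for c in ann.get(g, ())})
    nonconv = duplicated - converted
    rows: list[EnrichmentRow] = []
    for cat in categories:
        members = {g for g in duplicated if cat in ann.get(g, ())}
        ci = len(converted & members)
        co = len(converted) - ci
        ni = len(nonconv & members)
        no = len(nonconv) - ni
        table = np.array([[ci, co], [ni, no]])
        low = (ci + ni) < min_total
        if table.sum() == 0 or np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
            chi2, p = 0.0, 1.0
        else:
            chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        rows.append(EnrichmentRow(cat, ci, co, ni, no, float(chi2), float(p), low_count=low))
    if rows:
        ps = np.array([r.p for r in rows])
        order = np.argsort(ps)
        m = len(ps)
        bh = np.empty(m)
        running = 1.0
        for rank_pos in range(m - 1, -1, -1):
            i = order[rank_pos]
            running = min(running, ps[i] * m / (rank_pos + 1))
            bh[i] = running
        for r, adj in zip(rows, bh):
            r.p_bh = float(adj)
    return rows


def enrichment_to_frame(rows: Sequence[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame([{
        "category_id": r.category_id, "converted_in": r.converted_in,
        "converted_out": r.converted_out, "nonconverted_in": r.nonconverted_in,
        "nonconverted_out": r.nonconverted_out, "chi2": r.chi2, "p": r.p,
        "p_bh": r.p_bh, "low_count": r.low_count,
    } for r in rows])
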