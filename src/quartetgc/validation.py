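"""Reference validation scenarios with planted ground truth.

Each benchmark simulates quartets (or a genome set) under the package's
reference conditions, runs the corresponding detector, and scores the result
against the simulator's truth tables.  The same scenarios back the
acceptance test suite and the reproduction script, so the reported numbers
are always recomputed from scratch.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from scipy import stats

from .conversion import DetectorParams, assign_donor, detect_pcv, detect_wcv1, detect_wcv2
from .genome_stats import BinSeries, permutation_fold_test
from .pipeline import Pipeline, RunConfig
from .quartets import quartet_from_aligned
from .rates import CodonAlignment, ng86
from .simulate import SimConfig, simulate_quartet

ROLE_KEYS = ("p1", "p2", "o1", "o2")


def _sim_quartet(cfg, rng, qid, pattern="LCT"):
    seqs, truth = simulate_quartet(cfg, rng, quartet_id=qid)
    q = quartet_from_aligned(qid, pattern, truth.genes, [seqs[k] for k in ROLE_KEYS])
    return q, truth


def whole_conversion_benchmark(
    seed: int = 0, n_converted: int = 100, n_null: int = 400,
    params: DetectorParams = DetectorParams(),
) -> dict:
    """WCV sensitivity/false-positive benchmark with planted whole conversions.

    Simulates ``n_converted`` quartets with a planted whole-gene conversion
    and ``n_null`` without, under the reference conditions (paralog depth far
    exceeding the speciation depth), and runs both whole-gene detectors.
    Also records the NG86 corrected distances needed for the converted-vs-
    nonconverted distance-distortion comparison.
    """
    rng = np.random.default_rng(seed)
    conv_cfg = SimConfig(conversion_fraction=1.0,
                         conversion_kind_mix={"whole": 1.0, "partial": 0.0})
    null_cfg = SimConfig(conversion_fraction=0.0)
    rows = []
    for label, cfg, n in (("converted", conv_cfg, n_converted), ("null", null_cfg, n_null)):
        for i in range(n):
            q, truth = _sim_quartet(cfg, rng, f"{label}{i}")
            c1 = detect_wcv1(q, params, rng)
            c2 = detect_wcv2(q, params)
            pair_ps = {}
            pair_pn = {}
            for a, b, name in ((0, 1, "paralog"), (0, 2, "ortholog1"), (1, 3, "ortholog2")):
                r = ng86(CodonAlignment(
                    (q.genes[a], q.genes[b]),
                    (q.alignment.aligned_cds[a], q.alignment.aligned_cds[b])))
                pair_ps[name] = r.ps
                pair_pn[name] = r.pn
            rows.append({
                "converted": label == "converted",
                "wcv1": c1 is not None,
                "wcv2": c2 is not None,
                "ps": pair_ps, "pn": pair_pn,
            })
    conv = [r for r in rows if r["converted"]]
    null = [r for r in rows if not r["converted"]]
    out = {
        "n_converted": len(conv),
        "n_null": len(null),
        "wcv1_sensitivity": float(np.mean([r["wcv1"] for r in conv])),
        "wcv1_fpr": float(np.mean([r["wcv1"] for r in null])),
        "wcv2_sensitivity": float(np.mean([r["wcv2"] for r in conv])),
        "wcv2_fpr": float(np.mean([r["wcv2"] for r in null])),
        "wcv1_calls": int(sum(r["wcv1"] for r in rows)),
        "wcv2_calls": int(sum(r["wcv2"] for r in rows)),
        "rows": rows,
    }
    return out


def distance_distortion_summary(rows: list[dict]) -> dict:
    """Converted-vs-nonconverted Ps/Pn comparisons on benchmark rows.

    Conversion rejuvenates the paralog pair (lower paralog Ps) while the
    acceptor's ortholog distance inherits paralog-age divergence (higher
    ortholog Ps and Pn); one-sided Welch t-tests check both directions.
    """
    def collect(rows, which, metric):
        vals = []
        for r in rows:
            if which == "paralog":
                vals.append(r[metric]["paralog"])
            else:
                vals.extend((r[metric]["ortholog1"], r[metric]["ortholog2"]))
        return np.array([v for v in vals if np.isfinite(v)])

    conv = [r for r in rows if r["converted"]]
    null = [r for r in rows if not r["converted"]]
    par_c, par_n = collect(conv, "paralog", "ps"), collect(null, "paralog", "ps")
    ops_c, ops_n = collect(conv, "ortholog", "ps"), collect(null, "ortholog", "ps")
    opn_c, opn_n = collect(conv, "ortholog", "pn"), collect(null, "ortholog", "pn")
    t_par = stats.ttest_ind(par_c, par_n, equal_var=False, alternative="less")
    t_ops = stats.ttest_ind(ops_c, ops_n, equal_var=False, alternative="greater")
    t_opn = stats.ttest_ind(opn_c, opn_n, equal_var=False, alternative="greater")
    return {
        "paralog_ps_converted_mean": float(par_c.mean()),
        "paralog_ps_nonconverted_mean": float(par_n.mean()),
        "ortholog_ps_converted_mean": float(ops_c.mean()),
        "ortholog_ps_nonconverted_mean": float(ops_n.mean()),
        "ortholog_pn_converted_mean": float(opn_c.mean()),
        "ortholog_pn_nonconverted_mean": float(opn_n.mean()),
        "p_paralog_ps_less": float(t_par.pvalue),
        "p_ortholog_ps_greater": float(t_ops.pvalue),
        "p_ortholog_pn_greater": float(t_opn.pvalue),
    }


def partial_conversion_benchmark(
    seed: int = 0, n_converted: int = 200, n_null: int = 200,
    params: DetectorParams = DetectorParams(), boundary_tol_nt: int = 6,
) -> dict:
    """PCV segment-recovery benchmark with planted 30-300 nt conversions."""
    rng = np.random.default_rng(seed)
    conv_cfg = SimConfig(conversion_fraction=1.0,
                         conversion_kind_mix={"whole": 0.0, "partial": 1.0})
    null_cfg = SimConfig(conversion_fraction=0.0)
    n_boundary_ok = n_detected = 0
    min_len = None
    for i in range(n_converted):
        q, truth = _sim_quartet(conv_cfg, rng, f"p{i}")
        calls = detect_pcv(q, params, rng)
        ts, te = truth.segment
        for c in calls:
            min_len = c.segment_len_nt if min_len is None else min(min_len, c.segment_len_nt)
        if any(c.segment[1] > ts and c.segment[0] < te for c in calls):
            n_detected += 1
        if any(abs(c.segment[0] - ts) <= boundary_tol_nt
               and abs(c.segment[1] - te) <= boundary_tol_nt for c in calls):
            n_boundary_ok += 1
    n_null_called = 0
    for i in range(n_null):
        q, _ = _sim_quartet(null_cfg, rng, f"n{i}")
        calls = detect_pcv(q, params, rng)
        for c in calls:
            min_len = c.segment_len_nt if min_len is None else min(min_len, c.segment_len_nt)
        n_null_called += bool(calls)
    return {
        "n_converted": n_converted,
        "n_null": n_null,
        "detected_fraction": n_detected / n_converted,
        "boundary_accuracy": n_boundary_ok / n_converted,
        "null_call_rate": n_null_called / n_null,
        "min_reported_segment_nt": min_len,
    }


def donor_recovery_benchmark(
    seed: int = 0, n: int = 200, params: DetectorParams = DetectorParams()
) -> dict:
    """Donor/acceptor recovery on allotetraploid-pattern whole conversions."""
    rng = np.random.default_rng(seed)
    cfg = SimConfig(conversion_fraction=1.0,
                    conversion_kind_mix={"whole": 1.0, "partial": 0.0})
    role_map = {"p1": "Ama", "p2": "Amb"}
    n_called = n_unambiguous = n_correct = 0
    for i in range(n):
        q, truth = _sim_quartet(cfg, rng, f"d{i}", pattern="PRT")
        call = detect_wcv1(q, params, rng)
        if call is None:
            continue
        n_called += 1
        call = assign_donor(call, q)
        if call.donor_role == "ambiguous":
            continue
        n_unambiguous += 1
        n_correct += call.donor_role == role_map[truth.donor_role]
    return {
        "n": n,
        "n_called": n_called,
        "n_unambiguous": n_unambiguous,
        "donor_accuracy": n_correct / n_unambiguous if n_unambiguous else float("nan"),
    }


def permutation_calibration_benchmark(
    seed: int = 0, n_series: int = 500, n_bins: int = 20, rounds: int = 10_000
) -> dict:
    """Uniformity of the fold-test permutation p under an exchangeable null,
    plus the constructed series with a three-fold first bin."""
    rng = np.random.default_rng(seed)
    ps = []
    for _ in range(n_series):
        dup = rng.integers(50, 150, size=n_bins)
        conv = rng.binomial(dup, 0.1)
        s = BinSeries(1_000_000, dup, conv)
        s = permutation_fold_test(s, rounds=rounds, seed=int(rng.integers(2**31)))
        ps.append(s.perm_p)
    ks = stats.kstest(ps, "uniform")
    dup = np.full(n_bins, 100)
    conv = np.full(n_bins, 10)
    conv[0] = 30
    s3 = permutation_fold_test(BinSeries(1_000_000, dup, conv), rounds=rounds, seed=seed)
    s3b = permutation_fold_test(BinSeries(1_000_000, dup, conv.copy()), rounds=rounds, seed=seed)
    return {
        "n_series": n_series,
        "uniformity_ks_p": float(ks.pvalue),
        "threefold_fold": float(s3.fold_increase),
        "threefold_perm_p": float(s3.perm_p),
        "seed_reproducible": s3.perm_p == s3b.perm_p,
    }


def end_to_end_benchmark(seed: int = 0, outdir: str | Path = "scratch/e2e",
                         n_genes: int = 100) -> dict:
    """Full-pipeline run on a simulated two-genome set, twice, with scoring.

    Uses 2 genomes x 2 chromosomes x ``n_genes`` (400 genes total), planted
    conversion fraction 0.2, purifying selection (omega 0.3) so quartets
    pass the amino-acid identity filter, and modest noise.
    """
    outdir = Path(outdir)
    raw = {
        "paths": {"outdir": "run_a"},
        "simulate": {
            "n_genes_per_chromosome": n_genes,
            "conversion_fraction": 0.2,
            "omega": 0.3,
            "hit_fpr": 0.02,
            "inversion_rate": 0.5,
            "gene_loss_rate": 0.03,
        },
        "stats": {"perm_rounds": 10_000, "bin_width_bp": 100_000},
        "rng_seed": seed,
    }
    manifests = []
    for sub in ("run_a", "run_b"):
        cfg = RunConfig.from_dict({**raw, "paths": {"outdir": sub}}, base=outdir)
        Pipeline(cfg).run("all")
        manifests.append(json.loads((cfg.outdir / "manifest.json").read_text()))
    import pandas as pd

    out = Path(outdir) / "run_a"
    summary = pd.read_csv(out / "summary.tsv", sep="\t")
    truth = pd.read_csv(out / "sim" / "truth.tsv", sep="\t")
    n_kept = int(summary.quartets_kept[0])
    recovered = float(summary.conversion_rate_pct[0]) / 100.0
    planted = 0.2
    half_width = 1.96 * np.sqrt(planted * (1 - planted) / n_kept) if n_kept else float("nan")
    return {
        "n_kept_quartets": n_kept,
        "planted_fraction": planted,
        "planted_fraction_realized": float(truth.converted.mean()),
        "recovered_fraction": recovered,
        "binomial_ci_half_width": float(half_width),
        "within_ci": bool(abs(recovered - planted) <= half_width),
        "manifests_identical": manifests[0]["stages"] == manifests[1]["stages"],
    }
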