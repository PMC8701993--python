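"""Simulator correctness: determinism, planted truth, JC expectations, layout."""
import numpy as np
import pytest

from quartetgc.colinearity import BlockParams, detect_blocks, filter_hits
from quartetgc.rates import translate_cds
from quartetgc.simulate import (SimConfig, evolve, p_distance, random_cds,
                                simulate_genome_set, simulate_quartet)


class TestSimulateQuartet:
    def test_same_seed_reproduces_sequences_and_truth(self):
        cfg = SimConfig(rng_seed=5, conversion_fraction=0.5)
        s1, t1 = simulate_quartet(cfg, np.random.default_rng(5))
        s2, t2 = simulate_quartet(cfg, np.random.default_rng(5))
        assert s1 == s2
        assert (t1.converted, t1.kind, t1.segment) == (t2.converted, t2.kind, t2.segment)

    def test_zero_conversion_fraction_plants_nothing(self, rng):
        cfg = SimConfig(conversion_fraction=0.0)
        for i in range(10):
            _, t = simulate_quartet(cfg, rng)
            assert not t.converted and t.kind == "none"

    def test_sequences_translate_without_internal_stops(self, rng):
        cfg = SimConfig(conversion_fraction=1.0)
        for _ in range(5):
            seqs, _ = simulate_quartet(cfg, rng)
            for s in seqs.values():
                translate_cds(s)  # raises on internal stops

    def test_partial_segment_recorded_iff_partial(self, rng):
        whole = SimConfig(conversion_fraction=1.0,
                          conversion_kind_mix={"whole": 1.0, "partial": 0.0})
        part = SimConfig(conversion_fraction=1.0,
                         conversion_kind_mix={"whole": 0.0, "partial": 1.0})
        _, tw = simulate_quartet(whole, rng)
        _, tp = simulate_quartet(part, rng)
        assert tw.segment is None and tp.segment is not None
        lo, hi = tp.segment
        assert 0 <= lo < hi and hi - lo >= 30

    def test_mean_p_distance_matches_jc_closed_form(self, rng):
        # pairwise divergence 2*mu*t between two lineages split at depth t
        mu, t, L, reps = 1.0, 0.15, 300, 400
        expected = 0.75 * (1.0 - np.exp(-(4.0 / 3.0) * mu * 2 * t))
        obs = []
        for _ in range(reps):
            anc = random_cds(L // 3, rng)
            a = evolve(anc, t, rng, mu, omega=1.0)
            b = evolve(anc, t, rng, mu, omega=1.0)
            obs.append(p_distance(a, b))
        obs = np.asarray(obs)
        se = obs.std(ddof=1) / np.sqrt(reps)
        assert abs(obs.mean() - expected) < 3.5 * se + 1e-3

    def test_invalid_time_ordering_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(t_duplication=0.05, t_speciation=0.1)


class TestSimulateGenomeSet:
    def test_truth_and_fasta_are_mutually_consistent(self):
        cfg = SimConfig(n_genes_per_chromosome=12, gene_loss_rate=0.0)
        ds = simulate_genome_set(cfg, np.random.default_rng(2))
        for t in ds.truth:
            for g in t.genes:
                assert g in ds.cds
        mapped = {g.gene_id for m in ds.gene_maps.values() for g in m}
        assert mapped == set(ds.cds)

    def test_zero_noise_recovers_planted_blocks_exactly(self):
        cfg = SimConfig(n_genes_per_chromosome=20, hit_fpr=0.0,
                        inversion_rate=0.0, gene_loss_rate=0.0)
        ds = simulate_genome_set(cfg, np.random.default_rng(3))
        params = BlockParams()
        g1 = ds.gene_maps["G1"]
        hits = [h for h in ds.hits if h.query_id.startswith("G1") and h.subject_id.startswith("G1")]
        blocks = detect_blocks(g1, g1, filter_hits(hits, params), params)
        assert len(blocks) == 1
        assert blocks[0].n_anchors == 20 and blocks[0].orientation == "parallel"

    def test_planted_inversion_yields_inverted_block(self):
        cfg = SimConfig(n_genes_per_chromosome=30, hit_fpr=0.0,
                        inversion_rate=2.0, gene_loss_rate=0.0)
        ds = simulate_genome_set(cfg, np.random.default_rng(4))
        params = BlockParams()
        g1 = ds.gene_maps["G1"]
        hits = [h for h in ds.hits if h.query_id.startswith("G1") and h.subject_id.startswith("G1")]
        blocks = detect_blocks(g1, g1, filter_hits(hits, params), params)
        assert any(b.orientation == "inverted" for b in blocks)

    def test_family_inflation_is_removed_by_the_hit_filter(self):
        cfg = SimConfig(n_genes_per_chromosome=20, gene_family_inflation=1,
                        hit_fpr=0.0, gene_loss_rate=0.0)
        ds = simulate_genome_set(cfg, np.random.default_rng(6))
        params = BlockParams()
        kept = filter_hits(ds.hits, params)
        partners = {}
        for h in kept:
            partners.setdefault(h.query_id, set()).add(h.subject_id)
            partners.setdefault(h.subject_id, set()).add(h.query_id)
        assert all(len(p) < params.max_family_size for p in partners.values())

    def test_written_files_round_trip(self, tmp_path):
        from quartetgc.genome import read_gff3, read_hits
        cfg = SimConfig(n_genes_per_chromosome=8)
        ds = simulate_genome_set(cfg, np.random.default_rng(7))
        paths = ds.write(tmp_path)
        g1 = read_gff3(paths["G1.genes"], genome="G1")
        assert len(g1) == len(ds.gene_maps["G1"])
        for rec in ds.gene_maps["G1"]:
            back = g1[rec.gene_id]
            assert (back.start_bp, back.end_bp) == (rec.start_bp, rec.end_bp)
        hits = read_hits(paths["hits"])
        assert len(hits) == len(ds.hits)
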