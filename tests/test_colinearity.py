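"""Hit filtering, gap-constrained chaining and Ks block dating."""
import numpy as np
import pytest

from quartetgc.colinearity import (BlockParams, KsEventWindows, chain_anchors,
                                   date_block, detect_blocks, filter_hits,
                                   read_blocks, write_blocks)
from quartetgc.genome import ChromosomeMap, HomologyHit

from .oracles import chain_oracle


def make_map(n, genome="G", chrom="c1", prefix=None):
    prefix = prefix or genome
    return ChromosomeMap.from_positions(
        [(f"{prefix}{i}", chrom, i * 1000, i * 1000 + 500, "+") for i in range(n)],
        genome=genome)


def hit(q, s, evalue=1e-20, bitscore=500.0):
    return HomologyHit(q, s, evalue, bitscore)


class TestFilterHits:
    def test_evalue_and_bitscore_thresholds_are_strict(self):
        p = BlockParams()
        assert filter_hits([hit("a", "b", evalue=1e-4)], p) == []
        assert filter_hits([hit("a", "b", evalue=1e-10, bitscore=99.0)], p) == []
        assert filter_hits([hit("a", "b", evalue=1e-10, bitscore=100.0)], p) == []
        assert len(filter_hits([hit("a", "b", evalue=1e-6, bitscore=101.0)], p)) == 1

    def test_empty_input_yields_empty_output(self):
        assert filter_hits([], BlockParams()) == []

    def test_self_hits_removed(self):
        assert filter_hits([hit("a", "a")], BlockParams()) == []

    def test_gene_with_family_size_partners_loses_all_hits(self):
        p = BlockParams(max_family_size=50)
        hits = [hit("hub", f"g{i}") for i in range(50)]
        assert filter_hits(hits, p) == []
        assert len(filter_hits(hits[:49], p)) == 49

    def test_unknown_gene_id_is_a_hard_error(self):
        with pytest.raises(KeyError, match="ghost"):
            filter_hits([hit("a", "ghost")], BlockParams(), known_genes={"a", "b"})


class TestDetectBlocks:
    def test_perfect_diagonal_gives_one_parallel_block(self):
        ga, gb = make_map(5, "A"), make_map(5, "B")
        hits = [hit(f"A{i}", f"B{i}") for i in range(5)]
        blocks = detect_blocks(ga, gb, hits, BlockParams())
        assert len(blocks) == 1
        b = blocks[0]
        assert b.orientation == "parallel" and b.n_anchors == 5
        assert b.anchors == [(f"A{i}", f"B{i}") for i in range(5)]

    def test_three_anchor_chain_is_below_the_minimum(self):
        ga, gb = make_map(5, "A"), make_map(5, "B")
        hits = [hit(f"A{i}", f"B{i}") for i in range(3)]
        assert detect_blocks(ga, gb, hits, BlockParams()) == []

    def test_inverted_order_reports_inverted_orientation(self):
        ga, gb = make_map(6, "A"), make_map(6, "B")
        hits = [hit(f"A{i}", f"B{5 - i}") for i in range(6)]
        (b,) = detect_blocks(ga, gb, hits, BlockParams())
        assert b.orientation == "inverted" and b.n_anchors == 6

    def test_gap_constraint_splits_distant_runs(self):
        ga, gb = make_map(60, "A"), make_map(60, "B")
        hits = [hit(f"A{i}", f"B{i}") for i in list(range(4)) + list(range(56, 60))]
        blocks = detect_blocks(ga, gb, hits, BlockParams(max_gap=10))
        assert sorted(b.n_anchors for b in blocks) == [4, 4]

    def test_symmetric_under_genome_swap(self, rng):
        for _ in range(20):
            ga, gb = make_map(15, "A"), make_map(15, "B")
            pts = {(int(rng.integers(15)), int(rng.integers(15))) for _ in range(12)}
            hits = [hit(f"A{i}", f"B{j}") for i, j in pts]
            rev = [hit(f"B{j}", f"A{i}") for i, j in pts]
            fwd_blocks = detect_blocks(ga, gb, hits, BlockParams(max_gap=5))
            rev_blocks = detect_blocks(gb, ga, rev, BlockParams(max_gap=5))
            fwd = sorted(frozenset(b.anchors) for b in fwd_blocks)
            swp = sorted(frozenset((x, y) for y, x in b.anchors) for b in rev_blocks)
            assert fwd == swp

    def test_unknown_chromosome_gene_is_hard_error(self):
        ga, gb = make_map(5, "A"), make_map(5, "B")
        with pytest.raises(KeyError):
            detect_blocks(ga, gb, [hit("A0", "nowhere")], BlockParams())

    def test_matches_exhaustive_oracle_on_random_instances(self, rng):
        params = BlockParams(max_gap=4, min_anchors=4)
        for _ in range(15):
            n_hits = int(rng.integers(8, 18))
            pts = {(int(rng.integers(20)), int(rng.integers(20))) for _ in range(n_hits)}
            pts = sorted(pts)
            ids_a = {i: f"A{i}" for i in range(20)}
            ids_b = {i: f"B{i}" for i in range(20)}
            got = chain_anchors(pts, params.max_gap, params.min_anchors, ids_a, ids_b)
            want = chain_oracle(pts, params.max_gap, params.min_anchors, ids_a, ids_b)
            assert [sorted(c) for c in got] == [sorted(c) for c in want]

    def test_emitted_blocks_satisfy_monotonicity_and_gap_invariants(self, rng):
        ga, gb = make_map(30, "A"), make_map(30, "B")
        pts = {(int(rng.integers(30)), int(rng.integers(30))) for _ in range(40)}
        hits = [hit(f"A{i}", f"B{j}") for i, j in pts]
        params = BlockParams(max_gap=6)
        for b in detect_blocks(ga, gb, hits, params):
            ia = [int(x[0][1:]) for x in b.anchors]
            ib = [int(x[1][1:]) for x in b.anchors]
            assert ia == sorted(ia) and len(set(ia)) == len(ia)
            sb = sorted(ib)
            assert ib in (sb, sb[::-1]) and len(set(ib)) == len(ib)
            for (a1, b1), (a2, b2) in zip(zip(ia, ib), zip(ia[1:], ib[1:])):
                assert a2 - a1 - 1 <= params.max_gap
                assert abs(b2 - b1) - 1 <= params.max_gap


class TestDateBlock:
    def test_lct_window_contains_deep_median(self):
        ga, gb = make_map(3, "A"), make_map(3, "B")
        blocks = detect_blocks(ga, gb, [hit(f"A{i}", f"B{i}") for i in range(3)],
                               BlockParams(min_anchors=3))
        ks = {("A0", "B0"): 0.80, ("A1", "B1"): 0.86, ("A2", "B2"): 0.92}
        dated = date_block(blocks[0], ks, KsEventWindows.default())
        assert dated.median_ks == pytest.approx(0.86)
        assert dated.event == "LCT"

    def test_speciation_window_and_lower_median_rule(self):
        ga, gb = make_map(4, "A"), make_map(4, "B")
        (b,) = detect_blocks(ga, gb, [hit(f"A{i}", f"B{i}") for i in range(4)], BlockParams())
        ks = {(f"A{i}", f"B{i}"): v for i, v in enumerate([0.03, 0.05, 0.07, 0.09])}
        dated = date_block(b, ks, KsEventWindows.default())
        assert dated.median_ks == pytest.approx(0.05)  # lower of the two middles
        assert dated.event == "PRT_or_speciation"

    def test_missing_ks_leaves_block_unassigned(self):
        ga, gb = make_map(4, "A"), make_map(4, "B")
        (b,) = detect_blocks(ga, gb, [hit(f"A{i}", f"B{i}") for i in range(4)], BlockParams())
        dated = date_block(b, {}, KsEventWindows.default())
        assert dated.event == "unassigned" and dated.median_ks is None

    def test_out_of_window_median_is_other(self):
        ga, gb = make_map(4, "A"), make_map(4, "B")
        (b,) = detect_blocks(ga, gb, [hit(f"A{i}", f"B{i}") for i in range(4)], BlockParams())
        ks = {(f"A{i}", f"B{i}"): 0.45 for i in range(4)}
        assert date_block(b, ks, KsEventWindows.default()).event == "other"


def test_blocks_round_trip_through_tsv(tmp_path, rng):
    ga, gb = make_map(10, "A"), make_map(10, "B")
    hits = [hit(f"A{i}", f"B{i}") for i in range(10)]
    blocks = detect_blocks(ga, gb, hits, BlockParams())
    ks = {(f"A{i}", f"B{i}"): 0.8 for i in range(10)}
    blocks = [date_block(b, ks, KsEventWindows.default()) for b in blocks]
    write_blocks(blocks, tmp_path / "b.tsv", tmp_path / "a.tsv")
    back = read_blocks(tmp_path / "b.tsv", tmp_path / "a.tsv")
    assert len(back) == len(blocks)
    for x, y in zip(blocks, back):
        assert x.anchors == y.anchors and x.event == y.event
        assert x.median_ks == pytest.approx(y.median_ks)


def test_post_chaining_family_filter_drops_hub_anchors():
    """The post-chaining variant removes anchors of large families and
    discards blocks that fall below the anchor minimum."""
    from quartetgc.colinearity import remove_large_families_from_blocks

    ga, gb = make_map(6, "A"), make_map(6, "B")
    hits = [hit(f"A{i}", f"B{i}") for i in range(6)]
    (block,) = detect_blocks(ga, gb, hits, BlockParams())
    hub_hits = hits + [hit("A0", f"x{i}") for i in range(60)]
    params = BlockParams(max_family_size=50)
    (trimmed,) = remove_large_families_from_blocks([block], hub_hits, params)
    assert ("A0", "B0") not in trimmed.anchors and trimmed.n_anchors == 5
    small = BlockParams(max_family_size=50, min_anchors=6)
    assert remove_large_families_from_blocks([block], hub_hits, small) == []
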