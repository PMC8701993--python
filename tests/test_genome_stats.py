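"""Binning, permutation fold test, homogeneity, block association, enrichment."""
import numpy as np
import pytest
from scipy import stats

from quartetgc.colinearity import ColinearBlock
from quartetgc.genome import ChromosomeMap
from quartetgc.genome_stats import (BinSeries, bin_by_terminal_distance,
                                    block_length_association, chromosome_homogeneity,
                                    enrichment_chi2, permutation_fold_test)


def linear_map(positions, chrom="c1", genome="G"):
    return ChromosomeMap.from_positions(
        [(f"g{i}", chrom, p, p + 1000, "+") for i, p in enumerate(positions)],
        genome=genome)


class TestBinning:
    def test_direct_division_into_distance_bins(self):
        # genes 0.5 Mb and 1.5 Mb from the left terminus of a 10 Mb chromosome
        genes = linear_map([500_000, 1_500_000])
        s = bin_by_terminal_distance(genes, ["g0", "g1"], [],
                                     chrom_lengths={"c1": 10_000_000})
        assert s.duplicated[0] == 1 and s.duplicated[1] == 1

    def test_zero_converted_gives_zero_rates(self):
        genes = linear_map([500_000, 1_500_000])
        s = bin_by_terminal_distance(genes, ["g0", "g1"], [],
                                     chrom_lengths={"c1": 10_000_000})
        assert np.nansum(s.rates) == 0.0

    def test_right_arm_distance_measured_from_right_terminus(self):
        genes = linear_map([9_400_000])
        s = bin_by_terminal_distance(genes, ["g0"], [],
                                     chrom_lengths={"c1": 10_000_000})
        assert s.duplicated[0] == 1  # 0.6 Mb from the right end

    def test_occupancy_matches_direct_recount(self, rng):
        positions = sorted(rng.integers(0, 20_000_000, size=200).tolist())
        positions = list(dict.fromkeys(positions))
        genes = linear_map(positions)
        length = 20_000_000 + 2000
        s = bin_by_terminal_distance(genes, [f"g{i}" for i in range(len(positions))], [],
                                     chrom_lengths={"c1": length})
        recount = {}
        for p in positions:
            d = p if p < length // 2 else length - p
            recount[d // 1_000_000] = recount.get(d // 1_000_000, 0) + 1
        for b, c in recount.items():
            assert s.duplicated[b] == c
        assert s.duplicated.sum() == len(positions)

    def test_gene_beyond_chromosome_length_is_hard_error(self):
        genes = linear_map([500_000])
        with pytest.raises(ValueError):
            bin_by_terminal_distance(genes, ["g0"], [], chrom_lengths={"c1": 400_000})

    def test_converted_must_be_subset_of_duplicated(self):
        genes = linear_map([500_000])
        with pytest.raises(ValueError):
            bin_by_terminal_distance(genes, [], ["g0"])


class TestPermutationFoldTest:
    def test_equal_rates_give_fold_one_and_large_p(self):
        s = BinSeries(10**6, np.full(10, 100), np.full(10, 10))
        s = permutation_fold_test(s, rounds=2000, seed=0)
        assert s.fold_increase == pytest.approx(1.0)
        assert s.perm_p == pytest.approx(1.0)

    def test_three_fold_first_bin_matches_exchangeability(self):
        # with 20 exchangeable bins the 3x value lands first in 1/20 of
        # permutations, so the one-sided p settles at ~0.05
        dup = np.full(20, 100)
        conv = np.full(20, 10)
        conv[0] = 30
        s = permutation_fold_test(BinSeries(10**6, dup, conv), rounds=10_000, seed=1)
        assert s.fold_increase == pytest.approx(3.0)
        assert s.perm_p == pytest.approx(1 / 20, abs=0.01)

    def test_fixed_seed_reproduces_p_exactly(self):
        dup = np.full(12, 50)
        conv = np.array([9, 4, 5, 3, 6, 2, 5, 4, 3, 6, 4, 5])
        a = permutation_fold_test(BinSeries(10**6, dup, conv.copy()), rounds=5000, seed=42)
        b = permutation_fold_test(BinSeries(10**6, dup, conv.copy()), rounds=5000, seed=42)
        assert a.perm_p == b.perm_p and 0 < a.perm_p <= 1

    def test_zero_remaining_mean_reports_na(self):
        dup = np.full(5, 10)
        conv = np.array([3, 0, 0, 0, 0])
        s = permutation_fold_test(BinSeries(10**6, dup, conv), rounds=100, seed=0)
        assert s.fold_increase is None and s.perm_p is None

    def test_needs_two_occupied_bins(self):
        with pytest.raises(ValueError):
            permutation_fold_test(BinSeries(10**6, np.array([5]), np.array([1])))


class TestChromosomeHomogeneity:
    def _map(self, spec):
        rows = []
        for chrom, n in spec.items():
            rows += [(f"{chrom}_g{i}", chrom, i * 1000, i * 1000 + 500, "+")
                     for i in range(n)]
        return ChromosomeMap.from_positions(rows)

    def test_identical_rates_give_chi2_zero(self):
        genes = self._map({"c1": 100, "c2": 100})
        dup = [g.gene_id for g in genes]
        conv = [f"c1_g{i}" for i in range(10)] + [f"c2_g{i}" for i in range(10)]
        chi2, p, rates = chromosome_homogeneity(genes, dup, conv)
        assert chi2 == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_tenfold_rate_difference_is_significant(self):
        genes = self._map({"c1": 200, "c2": 200})
        dup = [g.gene_id for g in genes]
        conv = [f"c1_g{i}" for i in range(50)] + [f"c2_g{i}" for i in range(5)]
        chi2, p, _ = chromosome_homogeneity(genes, dup, conv)
        assert p < 0.01

    def test_margins_reproduce_input_totals(self):
        genes = self._map({"c1": 30, "c2": 50, "c3": 20})
        dup = [g.gene_id for g in genes]
        conv = [f"c2_g{i}" for i in range(7)]
        _, _, rates = chromosome_homogeneity(genes, dup, conv)
        assert (rates.converted + rates.nonconverted).sum() == 100
        assert rates.converted.sum() == 7


class TestBlockLengthAssociation:
    def _blocks(self, sizes):
        return [ColinearBlock(f"b{k}", "G", "G", "c1", "c2", "parallel",
                              [(f"b{k}a{i}", f"b{k}b{i}") for i in range(n)])
                for k, n in enumerate(sizes)]

    def test_flat_rates_give_near_zero_r_squared(self):
        blocks = self._blocks([5, 15, 60])
        table, r2 = block_length_association(blocks, set())
        assert table.n_blocks.sum() == 3
        assert r2 == 0.0

    def test_class_counts_partition_all_blocks(self):
        blocks = self._blocks([4, 8, 12, 55, 9])
        table, _ = block_length_association(blocks, set())
        assert table.n_blocks.sum() == len(blocks)

    def test_monotone_conversion_probability_gives_monotone_class_rates(self, rng):
        sizes = [5] * 20 + [20] * 20 + [60] * 10
        blocks = self._blocks(sizes)
        conv = set()
        for b in blocks:
            p = min(0.9, b.n_anchors / 70)
            for ga, _ in b.anchors:
                if rng.random() < p:
                    conv.add(ga)
        table, r2 = block_length_association(blocks, conv)
        rates = table.rate.tolist()
        assert rates[0] < rates[1] < rates[2]
        assert r2 > 0.1


class TestEnrichment:
    def test_hand_computed_pearson_statistic(self):
        # converted: 30 in / 70 out; nonconverted: 10 in / 90 out
        ann = {f"c{i}": ["GO:X"] for i in range(30)}
        ann.update({f"n{i}": ["GO:X"] for i in range(10)})
        converted = [f"c{i}" for i in range(100)]
        nonconv = [f"n{i}" for i in range(100)]
        rows = enrichment_chi2(ann, converted, converted + nonconv)
        (row,) = rows
        obs = np.array([[30, 70], [10, 90]])
        exp_chi2 = stats.chi2_contingency(obs, correction=False)[0]
        # cross-check against the explicit sum((O-E)^2/E)
        col = obs.sum(axis=0)
        rowt = obs.sum(axis=1)
        expected = np.outer(rowt, col) / obs.sum()
        assert exp_chi2 == pytest.approx(((obs - expected) ** 2 / expected).sum())
        assert row.chi2 == pytest.approx(exp_chi2)
        assert row.p < 0.001

    def test_proportional_table_gives_chi2_zero_p_one(self):
        ann = {f"c{i}": ["GO:Y"] for i in range(10)}
        ann.update({f"n{i}": ["GO:Y"] for i in range(10)})
        converted = [f"c{i}" for i in range(50)]
        dup = converted + [f"n{i}" for i in range(50)]
        (row,) = enrichment_chi2(ann, converted, dup)
        assert row.chi2 == pytest.approx(0.0) and row.p == pytest.approx(1.0)

    def test_low_count_category_is_flagged(self):
        ann = {"c0": ["GO:Z"]}
        (row,) = enrichment_chi2(ann, ["c0"], ["c0", "n0", "n1"])
        assert row.low_count

    def test_converted_gene_missing_from_duplicated_is_hard_error(self):
        with pytest.raises(ValueError):
            enrichment_chi2({}, ["x"], ["y"])
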