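"""Topology calls, WCV/PCV detectors and donor assignment."""
import numpy as np
import pytest

from quartetgc.conversion import (EXPECTED, OTHER, PARALOG_GROUPING, ConversionCall,
                                  DetectorParams, assign_donor, detect_pcv,
                                  detect_wcv1, detect_wcv2, quartet_topology)
from quartetgc.quartets import Quartet, quartet_from_aligned
from quartetgc.simulate import SimConfig, random_cds

from .conftest import make_quartet
from .oracles import topology_oracle


class TestQuartetTopology:
    def test_no_conversion_geometry_is_expected(self):
        assert quartet_topology(0.9, 0.9, 0.1, 0.1, 0.9, 0.9) == EXPECTED

    def test_converted_geometry_groups_paralogs(self):
        assert quartet_topology(0.01, 0.3, 0.3, 0.3, 0.35, 0.35) == PARALOG_GROUPING

    def test_exact_tie_resolves_to_expected(self):
        assert quartet_topology(0.2, 0.2, 0.2, 0.2, 0.2, 0.2) == EXPECTED

    def test_undefined_distance_raises(self):
        with pytest.raises(ValueError):
            quartet_topology(np.nan, 0.2, 0.2, 0.2, 0.2, 0.2)

    def test_agrees_with_direct_sum_oracle(self, rng):
        for _ in range(1000):
            d = rng.random(6)
            assert quartet_topology(*d) == topology_oracle(*d)


class TestWCV1:
    def test_identical_paralogs_called_with_full_support(self, rng):
        cds = random_cds(200, rng)
        far1 = random_cds(200, rng)
        far2 = random_cds(200, rng)
        q = quartet_from_aligned("q", "LCT", ("a1", "a2", "b1", "b2"),
                                 [cds, cds, far1, far2])
        call = detect_wcv1(q, rng=np.random.default_rng(0))
        assert call is not None and call.support == 1.0
        assert call.detector == "WCV-I" and call.segment is None

    def test_expected_topology_yields_no_call(self, null_cfg, rng):
        q, _ = make_quartet(null_cfg, rng)
        assert detect_wcv1(q, rng=rng) is None

    def test_bit_reproducible_with_fixed_seed(self, whole_conversion_cfg, rng):
        q, _ = make_quartet(whole_conversion_cfg, rng)
        c1 = detect_wcv1(q, rng=np.random.default_rng(7))
        c2 = detect_wcv1(q, rng=np.random.default_rng(7))
        assert c1 is not None and c1.support == c2.support


class TestWCV2:
    @staticmethod
    def _quartet_with_identities(id_par, id_o1, id_o2):
        """Proteins over 100 columns realizing given pairwise identities."""
        n = 100
        p1 = "A" * n
        p2 = "A" * round(n * id_par) + "C" * (n - round(n * id_par))
        o1 = "A" * round(n * id_o1) + "D" * (n - round(n * id_o1))
        k2 = round(n * id_o2)
        # o2 matches p2 over the first k2 columns of p2's pattern
        o2 = "".join(c if i < k2 else "E" for i, c in enumerate(p2))
        q = Quartet("q", "LCT", ("a1", "a2", "b1", "b2"))
        q.protein_alignment = (p1, p2, o1, o2)
        return q

    def test_strict_dominance_plus_topology_calls(self):
        q = self._quartet_with_identities(0.99, 0.90, 0.91)
        call = detect_wcv2(q)
        assert call is not None and call.support == 1.0 and call.segment is None

    def test_one_more_similar_ortholog_pair_blocks_the_call(self):
        q = self._quartet_with_identities(0.93, 0.95, 0.90)
        assert detect_wcv2(q) is None

    def test_every_call_is_topology_discordant_on_aa_distances(self, whole_conversion_cfg, rng):
        from quartetgc.conversion import _aa_identity
        for i in range(20):
            q, _ = make_quartet(whole_conversion_cfg, rng, qid=f"q{i}")
            call = detect_wcv2(q)
            if call is None:
                continue
            prots = q.protein_alignment
            d = {}
            for i2, j2 in ((0, 1), (2, 3), (0, 2), (1, 3), (0, 3), (1, 2)):
                d[(i2, j2)] = 1.0 - _aa_identity(prots[i2], prots[j2])
            assert quartet_topology(d[(0, 1)], d[(2, 3)], d[(0, 2)], d[(1, 3)],
                                    d[(0, 3)], d[(1, 2)]) == PARALOG_GROUPING


class TestPCV:
    def test_planted_window_yields_exactly_one_overlapping_segment(self, rng):
        # paralogs share a 60-nt window, elsewhere mutually diverged with
        # many opposing sites
        n = 120  # codons
        p1 = random_cds(n, rng)
        pre = random_cds(n, rng)  # acceptor before the overwrite
        start, end = 150, 210
        p2 = pre[:start] + p1[start:end] + pre[end:]
        # orthologs mirror the pre-conversion states
        q = quartet_from_aligned("q", "LCT", ("a1", "a2", "b1", "b2"),
                                 [p1, p2, p1, pre])
        calls = detect_pcv(q, rng=np.random.default_rng(0))
        assert len(calls) == 1
        (c,) = calls
        assert c.segment[1] > start and c.segment[0] < end
        assert c.segment_len_nt > 10

    def test_nine_nt_planted_run_is_below_threshold(self, rng):
        n = 120
        p1 = random_cds(n, rng)
        pre = random_cds(n, rng)
        p2 = pre[:150] + p1[150:159] + pre[159:]
        q = quartet_from_aligned("q", "LCT", ("a1", "a2", "b1", "b2"),
                                 [p1, p2, p1, pre])
        for c in detect_pcv(q, rng=np.random.default_rng(0)):
            assert not (c.segment[0] >= 140 and c.segment[1] <= 170)

    def test_short_alignment_returns_empty(self):
        q = quartet_from_aligned("q", "LCT", ("a1", "a2", "b1", "b2"), ["ATG"] * 4)
        assert detect_pcv(q) == []

    def test_segments_lie_within_alignment_and_exceed_10nt(self, partial_conversion_cfg, rng):
        for i in range(10):
            q, _ = make_quartet(partial_conversion_cfg, rng, qid=f"q{i}")
            for c in detect_pcv(q, rng=rng):
                assert 0 <= c.segment[0] < c.segment[1] <= len(q.alignment)
                assert c.segment_len_nt > 10

    def test_bit_reproducible_with_fixed_seed(self, partial_conversion_cfg, rng):
        q, _ = make_quartet(partial_conversion_cfg, rng)
        a = detect_pcv(q, rng=np.random.default_rng(3))
        b = detect_pcv(q, rng=np.random.default_rng(3))
        assert [(c.segment, c.support) for c in a] == [(c.segment, c.support) for c in b]


class TestAssignDonor:
    def test_copied_sequence_identifies_donor(self, rng):
        # Amb copied onto Ama: Ama now sits closer to Ai than to Ad
        anc = random_cds(150, rng)
        ama = amb = anc
        ad = random_cds(150, rng)
        ai = list(anc)
        for i in range(0, 450, 9):
            ai[i] = "ACGT"[(("ACGT".index(ai[i])) + 1) % 4]
        ai = "".join(ai)
        q = quartet_from_aligned("q", "PRT", ("Ama_g", "Amb_g", "Ad_g", "Ai_g"),
                                 [ama, amb, ad, ai])
        call = assign_donor(ConversionCall("q", "WCV-I"), q)
        assert (call.donor_role, call.acceptor_role) == ("Amb", "Ama")

    def test_symmetric_distances_are_ambiguous(self, rng):
        s = random_cds(100, rng)
        q = quartet_from_aligned("q", "PRT", ("Ama_g", "Amb_g", "Ad_g", "Ai_g"), [s] * 4)
        call = assign_donor(ConversionCall("q", "WCV-I"), q)
        assert call.donor_role == "ambiguous"

    def test_lct_pattern_without_outgroup_is_ambiguous(self, whole_conversion_cfg, rng):
        q, _ = make_quartet(whole_conversion_cfg, rng, pattern="LCT")
        call = assign_donor(ConversionCall(q.quartet_id, "WCV-I"), q)
        assert call.donor_role == call.acceptor_role == "ambiguous"
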