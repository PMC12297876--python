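"""Local alignment, EVE detection, tandem arrays and splice fusions."""

import numpy as np
import pytest
from scipy import stats

from ambidense.core import NucleotideSequence, rc
from ambidense.evescan import (
    attach_segments,
    detect_tandem_array,
    find_splice_fusion,
    local_align,
    scan_host_for_eves,
)
from ambidense.simulate import (
    build_rep_fusion_locus,
    plant_eve_locus,
    random_host,
)
from oracles import BASES, biopython_local_score, dna


class TestLocalAlign:
    def test_identical_500mers_full_identity(self):
        rng = np.random.default_rng(70)
        s = dna(rng, 500)
        hits = local_align(
            NucleotideSequence("q", s), NucleotideSequence("s", s)
        )
        assert len(hits) == 1
        h = hits[0]
        assert h.identity == 1.0
        assert h.score == 1000
        assert (h.query_start, h.query_end) == (1, 500)
        assert (h.subject_start, h.subject_end) == (1, 500)

    def test_score_equals_full_dp_oracle_on_short_pairs(self):
        """200 pairs up to 60 nt: optimal score equals an independent
        dynamic-programming implementation."""
        rng = np.random.default_rng(71)
        for i in range(200):
            n = int(rng.integers(20, 61))
            a = dna(rng, n)
            if i % 2:
                b = list(a)
                for _ in range(int(rng.integers(1, 8))):
                    p = int(rng.integers(n))
                    b[p] = BASES[rng.integers(4)]
                b = "".join(b)
            else:
                b = dna(rng, int(rng.integers(20, 61)))
            hits = local_align(
                NucleotideSequence("q", a), NucleotideSequence("s", b),
                min_score=1,
            )
            got = max((h.score for h in hits), default=0)
            assert got == biopython_local_score(a, b)

    def test_symmetric_score_under_swap(self):
        rng = np.random.default_rng(72)
        a, b = dna(rng, 300), dna(rng, 300)
        b = a[:150] + b[:150]
        ha = local_align(NucleotideSequence("q", a), NucleotideSequence("s", b))
        hb = local_align(NucleotideSequence("q", b), NucleotideSequence("s", a))
        assert max(h.score for h in ha) == max(h.score for h in hb)

    def test_seeded_path_finds_planted_segment_in_large_subject(self):
        rng = np.random.default_rng(73)
        q = dna(rng, 3000)
        subject = dna(rng, 30000)
        planted = q[500:1700]
        s = subject[:12000] + planted + subject[12000:]
        hits = local_align(
            NucleotideSequence("q", q), NucleotideSequence("s", s)
        )
        best = max(hits, key=lambda h: h.score)
        assert (best.query_start, best.query_end) == (501, 1700)
        assert (best.subject_start, best.subject_end) == (12001, 13200)
        assert best.identity == 1.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            local_align(NucleotideSequence("q", "A"), NucleotideSequence("s", ""))


class TestScanHostForEves:
    def test_eve_free_host_is_empty(self, default_genome):
        host = random_host(30000, seed=74)
        assert scan_host_for_eves(default_genome, [host]) == []

    def test_planted_ns1_integrant_found_and_labelled(self, default_truth):
        host = random_host(20000, seed=75)
        host, truth = plant_eve_locus(
            host, default_truth, (700, 1500), identity=0.8, copies=1, seed=76
        )
        hits = scan_host_for_eves(
            default_truth.genome, [host], annotation=default_truth.features
        )
        assert len(hits) == 1
        assert "NS1" in hits[0].label
        assert hits[0].identity == pytest.approx(0.8, abs=0.03)

    def test_itr_spanning_integrant_labelled_with_itr(self, default_truth):
        host = random_host(20000, seed=77)
        host, truth = plant_eve_locus(
            host, default_truth, (41, 1597), identity=0.75, copies=1, seed=78
        )
        hits = scan_host_for_eves(
            default_truth.genome, [host], annotation=default_truth.features
        )
        assert len(hits) == 1
        h = hits[0]
        assert h.viral_start < 207  # starts inside the 5' ITR
        assert "ITR5" in h.label and "NS1" in h.label and "NS2" in h.label

    def test_identity_monotone_across_planted_levels(self, default_truth):
        """Measured identity tracks requested identity (Spearman > 0.95)."""
        levels = np.linspace(0.65, 1.0, 8)
        measured = []
        for i, ident in enumerate(levels):
            host = random_host(6000, seed=100 + i)
            host, _ = plant_eve_locus(
                host, default_truth, (437, 1537), identity=float(ident),
                copies=1, seed=200 + i,
            )
            hits = scan_host_for_eves(default_truth.genome, [host])
            assert len(hits) == 1
            assert hits[0].identity == pytest.approx(ident, abs=0.03)
            measured.append(hits[0].identity)
        rho = stats.spearmanr(levels, measured).statistic
        assert rho > 0.95


class TestTandemArray:
    def test_single_hit_is_singleton_array(self, default_truth):
        host = random_host(10000, seed=80)
        host, _ = plant_eve_locus(
            host, default_truth, (437, 1537), identity=0.8, copies=1, seed=81
        )
        hits = scan_host_for_eves(default_truth.genome, [host])
        (arr,) = detect_tandem_array(hits)
        assert arr.copy_number == 1

    def test_29_head_to_tail_copies_recovered(self, default_truth):
        host = random_host(8000, seed=82)
        host, _ = plant_eve_locus(
            host, default_truth, (437, 1537), identity=0.75, copies=29, seed=83
        )
        hits = scan_host_for_eves(default_truth.genome, [host])
        assert len(hits) == 29
        attach_segments(hits, [host])
        (arr,) = detect_tandem_array(hits)
        assert arr.copy_number == 29
        assert arr.unit_length == pytest.approx(1101, abs=20)
        assert arr.mean_inter_copy_identity > 0.95  # verbatim copies

    def test_inverted_copy_breaks_the_chain(self, default_truth):
        """Four direct copies plus one inverted appended copy chain into a
        4-copy array and a separate singleton."""
        g = default_truth.genome
        unit = g.slice(437, 1537)
        rng = np.random.default_rng(84)
        host_res = dna(rng, 3000) + unit * 4 + rc(unit) + dna(rng, 3000)
        host = NucleotideSequence("host_inv", host_res)
        hits = scan_host_for_eves(g, [host])
        assert len(hits) == 5
        arrays = detect_tandem_array(hits)
        assert sorted(a.copy_number for a in arrays) == [1, 4]


class TestSpliceFusion:
    def test_printed_proportion_fixture_recovered(self, default_truth):
        """Synthetic locus built to the published proportions: 1271 nt
        GT..AG intron, 486 aa Rep-host fusion."""
        scaffold, info = build_rep_fusion_locus(default_truth, seed=85)
        hits = scan_host_for_eves(default_truth.genome, [scaffold])
        assert hits, "integrant must be detectable first"
        cands = find_splice_fusion(scaffold, hits[0])
        top = cands[0]
        assert top.aa_length == 486
        assert top.intron_length == 1271
        assert top.donor == info["donor"]
        assert top.acceptor == info["acceptor"]
        assert top.start_codon == info["start_codon"]
        # segment bookkeeping: coding nucleotides split across the junction
        assert top.viral_segment_nt + top.host_segment_nt == 3 * 486 + 3

    def test_planted_short_intron_recovered(self, default_truth):
        scaffold, info = build_rep_fusion_locus(
            default_truth, intron_length=300, fusion_aa=400, seed=86
        )
        hits = scan_host_for_eves(default_truth.genome, [scaffold])
        cands = find_splice_fusion(scaffold, hits[0])
        assert (cands[0].intron_length, cands[0].aa_length) == (300, 400)

    def test_no_acceptor_within_bounds_is_empty(self, default_truth):
        g = default_truth.genome
        rng = np.random.default_rng(87)
        eve_seq = g.slice(437, 1537)
        tail = "".join("CT"[i % 2] for i in range(400))  # AG-free tail
        host = NucleotideSequence("h", eve_seq + tail)
        hits = scan_host_for_eves(g, [host])
        cands = find_splice_fusion(
            host, hits[0], min_intron=60, max_intron=len(tail) + 100
        )
        acceptors_past_eve = [
            c for c in cands if c.acceptor > hits[0].host_end
        ]
        assert acceptors_past_eve == []
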