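"""ITR detection, flip-flop repeats, hairpin folding and G4 scanning."""

import numpy as np
import pytest

from ambidense.core import NucleotideSequence, rc, reverse_complement
from ambidense.simulate import GenomeSpec, build_ambisense_genome
from ambidense.telomere import (
    MIN_LOOP,
    PAIR_WEIGHTS,
    detect_flip_flop,
    detect_itr,
    fold_hairpin,
    scan_g_quadruplex,
)
from oracles import BASES, best_enumerated_score, brute_g4, dna


# ---------------------------------------------------------------------------
# ITR detection


def brute_itr(s, max_mismatch):
    """O(L^2) oracle: largest n whose prefix vs RC-suffix mismatch count
    stays within budget."""
    best = 0
    for n in range(1, len(s) // 2 + 1):
        mism = sum(a != b for a, b in zip(s[:n], rc(s[-n:])))
        if mism <= max_mismatch:
            best = n
    return best


class TestDetectItr:
    def test_default_genome_has_printed_itr(self, default_genome):
        res = detect_itr(default_genome)
        assert res is not None
        assert (res.length, res.mismatches) == (207, 0)
        assert res.left == (1, 207)
        assert res.right == (len(default_genome.residues) - 206,
                             len(default_genome.residues))

    def test_random_sequence_has_none(self):
        rng = np.random.default_rng(3)
        assert detect_itr(NucleotideSequence("x", dna(rng, 2000))) is None

    @pytest.mark.parametrize("planted", [80, 125])
    def test_planted_itr_matches_brute_force(self, planted):
        rng = np.random.default_rng(planted)
        core = dna(rng, 1500)
        left = dna(rng, planted)
        s = left + core + rc(left)
        # guarantee the repeat stops exactly at the planted length
        if core[0] == rc(core[-1:]):
            core = ("C" if core[0] != "C" else "A") + core[1:]
            s = left + core + rc(left)
        res = detect_itr(NucleotideSequence("x", s))
        assert res.length == brute_itr(s, 0) == planted

    def test_mismatch_budget(self):
        rng = np.random.default_rng(9)
        left = dna(rng, 100)
        s = left + dna(rng, 800) + rc(left)
        mutated = s[:50] + ("A" if s[50] != "A" else "C") + s[51:]
        assert detect_itr(NucleotideSequence("x", mutated)) .length == 50
        res = detect_itr(NucleotideSequence("x", mutated), max_mismatch=1)
        assert res.length == brute_itr(mutated, 1)

    def test_end_symmetry(self, default_genome):
        mirror = reverse_complement(default_genome)
        assert detect_itr(default_genome).length == detect_itr(mirror).length


# ---------------------------------------------------------------------------
# Flip-flop


class TestFlipFlop:
    def test_default_genome_printed_geometry(self, default_genome):
        res = detect_flip_flop(default_genome)
        assert res.relation == "inverted"
        assert res.repeat_length == 107
        assert res.inversion_length == 55
        assert res.inversion == (27, 81)
        assert res.flank_identity >= 0.9

    def test_degenerate_spec_is_direct(self):
        truth = build_ambisense_genome(
            GenomeSpec(flipflop_length=0, terminal_repeat_length=106, seed=4)
        )
        res = detect_flip_flop(truth.genome)
        assert res.relation == "direct"
        assert res.inversion is None
        assert res.repeat_length == 106

    def test_planted_31nt_inversion_in_90nt_repeats(self):
        truth = build_ambisense_genome(
            GenomeSpec(terminal_repeat_length=91, flipflop_length=31, seed=6)
        )
        res = detect_flip_flop(truth.genome)
        assert res.repeat_length == 91
        assert res.inversion_length == 31
        # exhaustive centred-segment oracle over the terminal windows
        s = truth.genome.residues
        D, E = s[:91], s[-91:]
        mism = [k for k in range(91) if D[k] != E[k]]
        t = min(min(mism), 90 - max(mism))
        assert res.inversion == (t + 1, 91 - t)

    def test_explicit_repeat_length(self, default_genome):
        res = detect_flip_flop(default_genome, repeat_length=107)
        assert res.inversion == (27, 81)


# ---------------------------------------------------------------------------
# Hairpin folding


class TestFoldHairpin:
    def test_unpairable_sequence(self):
        fold = fold_hairpin("AAAAA")
        assert fold.structure == "....."
        assert fold.score == 0

    def test_three_gc_stem(self):
        fold = fold_hairpin("GGGAAAACCC")
        assert fold.score == 9
        assert fold.structure == "(((....)))"
        assert fold.paired_bases == 6
        assert fold.loop_positions == [(4, 7)]

    def test_exhaustive_enumeration_small_sequences(self):
        """The DP optimum equals brute-force enumeration for all tested
        sequences up to 15 nt (500 random cases)."""
        rng = np.random.default_rng(12)
        for _ in range(500):
            s = dna(rng, int(rng.integers(5, 16)))
            assert fold_hairpin(s).score == best_enumerated_score(s)

    def test_balanced_brackets_and_min_loop(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            s = dna(rng, int(rng.integers(10, 80)))
            fold = fold_hairpin(s)
            depth = 0
            stack = []
            for i, ch in enumerate(fold.structure):
                if ch == "(":
                    stack.append(i)
                    depth += 1
                elif ch == ")":
                    j = stack.pop()
                    assert i - j > MIN_LOOP  # no loop under 3 unpaired bases
                    depth -= 1
                assert depth >= 0
            assert not stack

    def test_flip_and_flop_hairpins_fold_identically(self, default_genome):
        s = default_genome.residues
        assert fold_hairpin(s[:107]).structure == fold_hairpin(s[-107:]).structure

    def test_length_bounds(self):
        with pytest.raises(ValueError):
            fold_hairpin("A" * 501)


# ---------------------------------------------------------------------------
# G-quadruplex


class TestG4Scan:
    def test_no_gg_means_empty(self):
        seq = NucleotideSequence("x", "ATCATCATCATCATCATC")
        assert scan_g_quadruplex(seq) == []

    def test_canonical_quadruplex_single_maximal_hit(self):
        seq = NucleotideSequence("x", "GGGTGGGTGGGTGGG")
        hits = scan_g_quadruplex(seq)
        assert len(hits) == 1
        assert (hits[0].start, hits[0].end) == (1, 15)
        assert hits[0].g_run_length == 3
        assert hits[0].loops == (1, 1, 1)

    def test_brute_force_agreement_on_random_60mers(self):
        """Scan equals independent enumeration on 500 random 60-mers."""
        rng = np.random.default_rng(21)
        for _ in range(500):
            s = dna(rng, 60)
            seq = NucleotideSequence("x", s)
            got = [h for h in scan_g_quadruplex(seq) if h.strand == "+"]
            expected = brute_g4(s)
            assert len(got) == len(expected)
            assert {(h.start - 1, h.end - 1) for h in got} == {
                (a, b) for a, b, *_ in expected
            }

    def test_structural_invariants(self):
        rng = np.random.default_rng(22)
        s = "".join(
            "G" if rng.random() < 0.45 else BASES[rng.integers(4)]
            for _ in range(400)
        )
        for h in scan_g_quadruplex(NucleotideSequence("x", s)):
            assert h.g_run_length >= 2
            assert h.end - h.start + 1 <= 45
            assert all(0 <= l <= 36 for l in h.loops)
            assert h.end - h.start + 1 == 4 * h.g_run_length + sum(h.loops)

    def test_planted_tracts_flank_the_hairpins(self, default_truth):
        """G4s sit downstream of the 5' hairpin and upstream of the 3' one."""
        genome = default_truth.genome
        L = len(genome.residues)
        hits = scan_g_quadruplex(genome)
        assert any(
            h.strand == "+" and 107 < h.start and h.end <= 207 for h in hits
        )
        assert any(
            h.strand == "-" and L - 207 < h.start and h.end <= L - 107
            for h in hits
        )
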