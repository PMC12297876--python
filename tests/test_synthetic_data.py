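"""Generator-detector closure, read simulation and EVE planting."""

import numpy as np
import pytest

from ambidense.annotate import build_transcription_map, find_orfs
from ambidense.core import rc
from ambidense.evescan import local_align
from ambidense.simulate import (
    GenomeSpec,
    ReadSimParams,
    SpecLayoutError,
    build_ambisense_genome,
    plant_eve_locus,
    random_host,
    simulate_rca_reads,
    write_truth,
)
from ambidense.telomere import detect_flip_flop, detect_itr
from oracles import random_valid_spec


class TestBuildGenome:
    def test_default_spec_matches_printed_architecture(self, default_truth):
        assert len(default_truth.genome.residues) == 5123
        itr5 = default_truth.features_of(
            type(default_truth.features[0].kind).ITR5
        )[0]
        assert (itr5.start, itr5.end) == (1, 207)

    def test_determinism_byte_identical(self, tmp_path):
        a = build_ambisense_genome(GenomeSpec(seed=42))
        b = build_ambisense_genome(GenomeSpec(seed=42))
        assert a.genome.residues == b.genome.residues
        pa = write_truth(a, tmp_path / "a")
        pb = write_truth(b, tmp_path / "b")
        for key in pa:
            assert pa[key].read_bytes() == pb[key].read_bytes()

    def test_infeasible_spec_raises_constructively(self):
        with pytest.raises(SpecLayoutError, match="ITR"):
            build_ambisense_genome(
                GenomeSpec(itr_length=120, terminal_repeat_length=107)
            )

    def test_generator_detector_closure_random_specs(self):
        """Detectors recover every planted truth value exactly (8 specs here;
        the acceptance suite runs 20)."""
        rng = np.random.default_rng(77)
        for _ in range(8):
            spec = random_valid_spec(rng)
            truth = build_ambisense_genome(spec)
            genome = truth.genome
            itr = detect_itr(genome)
            assert (itr.length, itr.mismatches) == (spec.itr_length, 0)
            ff = detect_flip_flop(genome)
            assert ff.repeat_length == spec.terminal_repeat_length
            assert ff.inversion_length == spec.flipflop_length
            orfs = find_orfs(genome, min_aa=min(100, spec.ns2_length))
            assert {(o.strand, o.aa_length) for o in orfs} == {
                ("+", spec.ns1_length),
                ("+", spec.ns2_length),
                ("-", spec.vp_length),
            }
            tmap = build_transcription_map(
                genome, orfs, min_aa=min(100, spec.ns2_length)
            )
            assert tmap.truncated_vp.aa_length == spec.truncated_vp_length
            assert tmap.ns_unit.leader_uaug_count == 3
            assert tmap.leaky_scan.verdict == "leaky_scanning_plausible"

    def test_haplotype_snps_recorded(self):
        truth = build_ambisense_genome(GenomeSpec(seed=9, haplotype_snps=5))
        assert len(truth.haplotypes) == 5
        for pos, ref, alt, freq in truth.haplotypes:
            assert truth.genome.residues[pos - 1] == ref
            assert alt != ref
            assert freq == pytest.approx(0.3)


class TestReadSimulation:
    def test_uniform_depth_within_three_sd(self, default_truth):
        params = ReadSimParams(mean_depth=30, terminal_decay=1.0, seed=2)
        reads = simulate_rca_reads(default_truth, params)
        depth = np.zeros(len(default_truth.genome.residues))
        for r in reads:
            pos = int(r.description.split("pos=")[1].split()[0])
            depth[pos - 1 : pos - 1 + len(r.residues)] += 1
        sd = np.sqrt(30)
        assert np.all(np.abs(depth - 30) <= 3.2 * sd)

    def test_terminal_decay_lowers_itr_coverage(self, default_truth):
        params = ReadSimParams(mean_depth=30, terminal_decay=0.2, seed=3)
        reads = simulate_rca_reads(default_truth, params)
        depth = np.zeros(len(default_truth.genome.residues))
        for r in reads:
            pos = int(r.description.split("pos=")[1].split()[0])
            depth[pos - 1 : pos - 1 + len(r.residues)] += 1
        itr = np.r_[depth[:207], depth[-207:]]
        core = depth[207:-207]
        assert np.median(itr) < np.median(core)

    def test_host_fraction(self, default_truth):
        host = random_host(30000, seed=5)
        params = ReadSimParams(mean_depth=30, host_fraction=0.5, seed=4)
        reads = simulate_rca_reads(default_truth, params, host)
        n_host = sum("origin=host" in r.description for r in reads)
        assert n_host / len(reads) == pytest.approx(0.5, abs=0.02)

    def test_host_required_when_fraction_positive(self, default_truth):
        with pytest.raises(ValueError, match="host"):
            simulate_rca_reads(
                default_truth, ReadSimParams(host_fraction=0.5, seed=1)
            )

    def test_read_length_exceeding_genome_rejected(self, default_truth):
        with pytest.raises(ValueError, match="read_length"):
            simulate_rca_reads(
                default_truth, ReadSimParams(read_length=10000, seed=1)
            )

    def test_fixed_seed_reproducible(self, default_truth):
        p = ReadSimParams(mean_depth=10, substitution_rate=0.01, seed=11)
        a = simulate_rca_reads(default_truth, p)
        b = simulate_rca_reads(default_truth, p)
        assert [(r.id, r.residues) for r in a] == [(r.id, r.residues) for r in b]

    def test_haplotype_frequency_observed(self):
        truth = build_ambisense_genome(
            GenomeSpec(seed=9, haplotype_snps=3, haplotype_freq=0.4)
        )
        reads = simulate_rca_reads(
            truth, ReadSimParams(mean_depth=60, terminal_decay=1.0, seed=12)
        )
        pos, ref, alt, freq = truth.haplotypes[0]
        alt_n = tot = 0
        for r in reads:
            if "origin=viral" not in r.description or "rc=1" in r.description:
                continue
            start = int(r.description.split("pos=")[1].split()[0])
            i = pos - start
            if 0 <= i < len(r.residues):
                tot += 1
                alt_n += r.residues[i] == alt
        assert tot > 10
        assert alt_n / tot == pytest.approx(freq, abs=0.2)

    def test_paired_reads_are_proper_pairs(self, default_truth):
        params = ReadSimParams(paired=True, mean_depth=10, seed=6)
        reads = simulate_rca_reads(default_truth, params)
        mates = {}
        for r in reads:
            base, _, mate = r.id.partition("/")
            mates.setdefault(base, []).append(mate)
        assert all(sorted(v) == ["1", "2"] for v in mates.values())


class TestEvePlanting:
    def test_identity_one_is_verbatim(self, default_truth):
        host = random_host(5000, seed=1)
        host2, truth = plant_eve_locus(
            host, default_truth, (100, 600), identity=1.0, copies=1, seed=2
        )
        locus = truth.eve_loci[-1]
        planted = host2.slice(locus.start, locus.end)
        assert planted == default_truth.genome.slice(100, 600)

    def test_planted_identity_measured_by_alignment(self, default_truth):
        host = random_host(8000, seed=3)
        host2, truth = plant_eve_locus(
            host, default_truth, (41, 1597), identity=0.75, copies=1, seed=4
        )
        locus = truth.eve_loci[-1]
        from ambidense.core import NucleotideSequence

        viral = NucleotideSequence("v", default_truth.genome.slice(41, 1597))
        hits = local_align(viral, host2, min_score=50)
        best = max(hits, key=lambda h: h.score)
        assert best.identity == pytest.approx(0.75, abs=0.03)

    def test_identity_monotone_in_request(self, default_truth):
        """Lower requested identity never yields higher measured identity."""
        host = random_host(4000, seed=5)
        measured = []
        from ambidense.core import NucleotideSequence

        viral = NucleotideSequence("v", default_truth.genome.slice(300, 1300))
        for ident in (0.65, 0.75, 0.85, 0.95, 1.0):
            h2, truth = plant_eve_locus(
                random_host(4000, seed=5), default_truth, (300, 1300),
                identity=ident, copies=1, seed=6,
            )
            locus = truth.eve_loci[-1]
            hits = local_align(viral, h2, min_score=40)
            measured.append(max(h.identity for h in hits))
        assert all(b >= a - 0.03 for a, b in zip(measured, measured[1:]))

    def test_bounds_checked(self, default_truth):
        host = random_host(2000, seed=7)
        with pytest.raises(IndexError):
            plant_eve_locus(host, default_truth, (100, 99999))
        with pytest.raises(ValueError, match="identity"):
            plant_eve_locus(host, default_truth, (1, 100), identity=0.3)
        with pytest.raises(ValueError, match="copies"):
            plant_eve_locus(host, default_truth, (1, 100), copies=0)
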