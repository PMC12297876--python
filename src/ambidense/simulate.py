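"""Truth-annotated synthetic data: ambisense densovirus-like genomes,
RCA-style short-read sets, and host genomes carrying planted integrants.

The generator's default :class:`GenomeSpec` reproduces the architecture of a
5123 nt homotelomeric ambisense densovirus genome: perfect 207 nt inverted
terminal repeats whose outermost 107 nt are hairpin-forming imperfect direct
repeats differing by a 55 nt flip-flop inversion, a rightward NS
transcription unit (NS1/Rep of 719 aa with an internal leaky-scanned NS2 of
332 aa), a converging leftward VP unit (749 aa, with an internal promoter
yielding a 435 aa N-terminally truncated VP), TATA / TATA-like / poly(A)
elements at the published spacings, G-quadruplex tracts flanking both
hairpins, HuH and YuxK nickase motifs in NS1, and a unique 372 bp diagnostic
PCR amplicon in the VP gene.

Because a perfect ITR forces the 3'-terminal window to be the exact reverse
complement of the 5'-terminal window, every element planted in one telomere
appears mirrored (reverse-complemented) in the other; the generator plants
the 5' copies and derives the 3' ones.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .core import (
    CODON_TABLE,
    Feature,
    FeatureKind,
    NucleotideSequence,
    STOP_CODONS,
    rc,
    write_fasta,
    write_features,
)

_BASES = np.array(list("ACGT"))
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

SENSE_CODONS = sorted(set(CODON_TABLE) - STOP_CODONS)
CODONS_BY_AA: dict[str, list[str]] = {}
for codon, aa in CODON_TABLE.items():
    CODONS_BY_AA.setdefault(aa, []).append(codon)
for _aa in CODONS_BY_AA:
    CODONS_BY_AA[_aa].sort()

#: diagnostic PCR primers targeting the VP gene (amplicon 372 bp)
PRIMER_FWD = "GCAGAAAGTTCTTTGGCGGG"
PRIMER_REV = "CCTGTGTCCTTGGGTACGAC"
AMPLICON_BP = 372

G4_TRACT = "GGGTGGGTGGGTGGG"


class SpecLayoutError(ValueError):
    """Raised when planted elements cannot coexist under a GenomeSpec."""


@dataclass
class GenomeSpec:
    total_length: int = 5123
    itr_length: int = 207
    terminal_repeat_length: int = 107
    flipflop_length: int = 55
    ns1_length: int = 719
    ns2_length: int = 332
    vp_length: int = 749
    truncated_vp_length: int = 435
    tata_motif: str = "TATAAA"
    tata_like_motif: str = "TAAATAAA"
    polya_motif: str = "AATAAA"
    g4_runs: int = 1
    haplotype_snps: int = 0
    haplotype_freq: float = 0.3
    plant_primer_sites: bool = True
    seed: int = 0


@dataclass
class EveLocus:
    scaffold: str
    start: int
    end: int
    viral_interval: tuple[int, int]
    identity: float
    copies: int
    unit_length: int
    intron: tuple[int, int] | None = None


@dataclass
class SyntheticTruth:
    genome: NucleotideSequence
    features: list[Feature]
    haplotypes: list[tuple[int, str, str, float]]
    eve_loci: list[EveLocus]
    spec: GenomeSpec

    def features_of(self, kind: FeatureKind) -> list[Feature]:
        return [f for f in self.features if f.kind is kind]


@dataclass
class ReadSimParams:
    read_length: int = 150
    paired: bool = False
    insert_mean: int = 350
    insert_sd: int = 40
    mean_depth: float = 30.0
    terminal_decay: float = 0.2
    substitution_rate: float = 0.0
    host_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("terminal_decay", "substitution_rate", "host_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")


# ---------------------------------------------------------------------------
# Layout


@dataclass
class _Layout:
    L: int
    itr: int
    R: int
    f: int
    arm: int
    flip: tuple[int, int]
    tata5: tuple[int, int]
    g4s: list[tuple[int, int]]
    uaugs: list[int]
    ns_tata_like: tuple[int, int]
    ns1_start: int
    ns1_stop: tuple[int, int]
    ns2_start: int
    ns2_prestop: tuple[int, int]
    ns2_stop: tuple[int, int]
    ns_polya: tuple[int, int]
    vp_aug_end: int
    vp_stop: tuple[int, int]
    vp_polya: tuple[int, int]
    trunc_end: int
    internal_tata_like: tuple[int, int]
    primer_fwd: tuple[int, int] | None
    primer_rev: tuple[int, int] | None
    vp_uaug: tuple[int, int]


def _layout(spec: GenomeSpec) -> _Layout:
    L, itr, R, f = (
        spec.total_length,
        spec.itr_length,
        spec.terminal_repeat_length,
        spec.flipflop_length,
    )
    problems = []
    if not (itr >= R >= f >= 0):
        problems.append("itr_length >= terminal_repeat_length >= flipflop_length")
    if f and f % 2 == 0:
        problems.append("flipflop_length must be odd (or zero)")
    if f == 0 and R % 2:
        problems.append("terminal_repeat_length must be even when flipflop_length is 0")
    if f and (R - f) % 2:
        problems.append("terminal repeat arms must have equal length")
    if R < 50:
        problems.append("terminal_repeat_length below the detectable minimum (50)")
    arm = (R - f) // 2
    if arm < 16:
        problems.append("terminal repeat arms too short to hold the ITR TATA box")
    if f and f < 9:
        problems.append("flip-flop inversion shorter than its pinned stem/loop core")
    g4s = [(R + 8 + 25 * j, R + 22 + 25 * j) for j in range(spec.g4_runs)]
    if g4s and g4s[-1][1] > itr - 5:
        problems.append("G-quadruplex tracts do not fit inside the ITR")
    ns1_start = itr + 230
    ns1_stop = (ns1_start + 3 * spec.ns1_length, ns1_start + 3 * spec.ns1_length + 2)
    ns2_start = ns1_start + 199
    ns2_stop = (ns2_start + 3 * spec.ns2_length, ns2_start + 3 * spec.ns2_length + 2)
    if ns2_stop[1] > ns1_stop[0] - 1:
        problems.append("NS2 ORF does not fit inside the NS1 ORF")
    if spec.ns1_length < 311:
        problems.append("NS1 too short to carry the HuH (256) and YuxK (307) motifs")
    ns2_stop_rel = (ns2_stop[0] - ns1_start, ns2_stop[1] - ns1_start)
    for lo, hi, name in ((765, 773, "HuH"), (918, 929, "YuxK")):
        if ns2_stop_rel[0] <= hi and lo <= ns2_stop_rel[1]:
            problems.append(f"NS2 stop codon collides with the NS1 {name} motif")
    ns_polya = (ns1_stop[1] + 4, ns1_stop[1] + 9)
    va = L - itr - 12
    vp_stop = (va - 3 * spec.vp_length - 2, va - 3 * spec.vp_length)
    vp_polya = (vp_stop[0] - 15, vp_stop[0] - 10)
    if vp_polya[0] <= ns_polya[1] + 1:
        problems.append("NS and VP units collide mid-genome")
    if not (1 <= spec.truncated_vp_length < spec.vp_length):
        problems.append("truncated VP length must be positive and shorter than VP")
    trunc_end = va - 3 * (spec.vp_length - spec.truncated_vp_length)
    internal = (trunc_end + 49, trunc_end + 56)
    if internal[1] > va - 3:
        problems.append("internal TATA-like element collides with the VP start codon")
    primer_fwd = primer_rev = None
    if spec.plant_primer_sites:
        pf = vp_stop[0] + 445
        if pf + 371 > trunc_end - 13:
            pf = vp_stop[0] + 10
        if pf + 371 > trunc_end - 13 or pf < vp_stop[1] + 4:
            problems.append("diagnostic primer sites do not fit in the VP gene")
        else:
            primer_fwd = (pf, pf + 19)
            primer_rev = (pf + 352, pf + 371)
    uaugs = [itr + 8, itr + 33, itr + 58]
    if problems:
        raise SpecLayoutError("; ".join(problems))
    return _Layout(
        L=L, itr=itr, R=R, f=f, arm=arm,
        flip=(arm + 1, R - arm),
        tata5=(R - 14, R - 9),
        g4s=g4s,
        uaugs=uaugs,
        ns_tata_like=(ns1_start - 55, ns1_start - 48),
        ns1_start=ns1_start,
        ns1_stop=ns1_stop,
        ns2_start=ns2_start,
        ns2_prestop=(ns2_start - 3, ns2_start - 1),
        ns2_stop=ns2_stop,
        ns_polya=ns_polya,
        vp_aug_end=va,
        vp_stop=vp_stop,
        vp_polya=vp_polya,
        trunc_end=trunc_end,
        internal_tata_like=internal,
        primer_fwd=primer_fwd,
        primer_rev=primer_rev,
        vp_uaug=(va + 1, va + 6),
    )


# ---------------------------------------------------------------------------
# Constrained coding-region samplers


def _sample_coding(
    rng: np.random.Generator,
    n_codons: int,
    fixed: dict[int, str],
    aa_codon_sets: dict[int, list[str]],
    no_atg_zone: tuple[int, int] | None,
    alt_frame_offset: int | None,
    alt_frame_nostop: tuple[int, int] | None,
) -> str:
    """Sample ``n_codons`` codons (last one a stop) subject to constraints.

    ``fixed`` maps 0-based region positions to bases.  ``no_atg_zone`` bans
    ATG triples starting inside the (0-based, inclusive) range.  When
    ``alt_frame_offset`` is given, codons of the overlapping second frame
    starting inside ``alt_frame_nostop`` must not be stop codons.
    """
    length = 3 * n_codons
    for _restart in range(40):
        out: list[str] = []
        ok = True
        for ci in range(n_codons):
            if ci == n_codons - 1:
                cands = ["TAA"]
            else:
                cands = aa_codon_sets.get(ci, SENSE_CODONS)
            base = 3 * ci
            cands = [
                c
                for c in cands
                if all(
                    fixed.get(base + k, c[k]) == c[k] for k in range(3)
                )
            ]
            order = rng.permutation(len(cands))
            chosen = None
            prefix = "".join(out)
            for oi in order:
                cand = cands[oi]
                window_start = max(0, base - 2)
                seq = prefix[window_start:] + cand
                good = True
                if no_atg_zone is not None:
                    lo, hi = no_atg_zone
                    for t in range(max(lo, base - 2), min(hi, base + 2) + 1):
                        rel = t - window_start
                        if rel + 3 <= len(seq) and seq[rel : rel + 3] == "ATG":
                            good = False
                            break
                if good and alt_frame_offset is not None:
                    lo, hi = alt_frame_nostop
                    q = alt_frame_offset
                    while q < lo:
                        q += 3
                    for t in range(q, base + 3, 3):
                        if t < lo or t > hi or t < base - 2:
                            continue
                        rel = t - window_start
                        if rel >= 0 and rel + 3 <= len(seq):
                            if seq[rel : rel + 3] in STOP_CODONS:
                                good = False
                                break
                if good:
                    chosen = cand
                    break
            if chosen is None:
                ok = False
                break
            out.append(chosen)
        if ok:
            return "".join(out)
    raise RuntimeError("coding-region sampler failed to satisfy constraints")


def _ns_constraints(spec: GenomeSpec, lay: _Layout):
    rel = lambda p: p - lay.ns1_start
    fixed: dict[int, str] = {}
    for (a, _b), motif in (
        (lay.ns2_prestop, "TAA"),
        ((lay.ns2_start, lay.ns2_start + 2), "ATG"),
        (lay.ns2_stop, "TAA"),
    ):
        for k, ch in enumerate(motif):
            fixed[rel(a) + k] = ch
    aa_sets = {
        0: ["ATG"],
        # HuH nickase motif H-V-H at aa 256..258
        255: CODONS_BY_AA["H"],
        256: CODONS_BY_AA["V"],
        257: CODONS_BY_AA["H"],
        # YuxK motif Y-I-Q-K at aa 307..310
        306: CODONS_BY_AA["Y"],
        307: CODONS_BY_AA["I"],
        308: CODONS_BY_AA["Q"],
        309: CODONS_BY_AA["K"],
    }
    return dict(
        n_codons=spec.ns1_length + 1,
        fixed=fixed,
        aa_codon_sets=aa_sets,
        no_atg_zone=(1, rel(lay.ns2_start) - 1),
        alt_frame_offset=rel(lay.ns2_start) % 3,
        alt_frame_nostop=(rel(lay.ns2_start) + 3, rel(lay.ns2_stop[0]) - 3),
    )


def _vp_constraints(spec: GenomeSpec, lay: _Layout):
    va = lay.vp_aug_end
    q0 = lambda p: va - p  # forward coord -> 0-based mRNA position
    fixed: dict[int, str] = {}
    # internal TATA-like element, read in the leftward (mRNA) sense
    for k, ch in enumerate(spec.tata_like_motif):
        fixed[q0(lay.internal_tata_like[1]) + k] = ch
    if lay.primer_fwd is not None:
        for k, ch in enumerate(rc(PRIMER_FWD)):
            fixed[q0(lay.primer_fwd[1]) + k] = ch
        for k, ch in enumerate(PRIMER_REV):
            fixed[q0(lay.primer_rev[1]) + k] = ch
    aa_sets = {
        0: ["ATG"],
        spec.vp_length - spec.truncated_vp_length: ["ATG"],
    }
    return dict(
        n_codons=spec.vp_length + 1,
        fixed=fixed,
        aa_codon_sets=aa_sets,
        no_atg_zone=(q0(lay.trunc_end + 24), q0(lay.trunc_end + 1)),
        alt_frame_offset=None,
        alt_frame_nostop=None,
    )


def _ns_region(rng: np.random.Generator, spec: GenomeSpec, lay: _Layout) -> str:
    return _sample_coding(rng, **_ns_constraints(spec, lay))


def _vp_mrna(rng: np.random.Generator, spec: GenomeSpec, lay: _Layout) -> str:
    return _sample_coding(rng, **_vp_constraints(spec, lay))


def _codon_ok(region: str, ci: int, cand: str, cons: dict) -> bool:
    """Would replacing 0-based codon ``ci`` of ``region`` with ``cand`` keep
    the region's planted constraints (fixed bases, ATG-free zone, second
    reading frame free of stops)?"""
    base = 3 * ci
    for k in range(3):
        if cons["fixed"].get(base + k, cand[k]) != cand[k]:
            return False
    if cand in STOP_CODONS and ci != cons["n_codons"] - 1:
        return False
    if ci in cons["aa_codon_sets"] and cand not in cons["aa_codon_sets"][ci]:
        return False
    trial = region[:base] + cand + region[base + 3 :]
    zone = cons["no_atg_zone"]
    if zone is not None:
        for t in range(max(zone[0], base - 2), min(zone[1], base + 2) + 1):
            if trial[t : t + 3] == "ATG":
                return False
    if cons["alt_frame_offset"] is not None:
        lo, hi = cons["alt_frame_nostop"]
        for t in range(base - 2, base + 3):
            if (
                (t - cons["alt_frame_offset"]) % 3 == 0
                and lo <= t <= hi
                and trial[t : t + 3] in STOP_CODONS
            ):
                return False
    return True


def _repair_spurious_orfs(
    g: list[str], spec: GenomeSpec, lay: _Layout, rng: np.random.Generator
) -> bool:
    """Plant stops that break chance ORFs outside the intended three.

    Random codon filling occasionally leaves long open frames on the
    unconstrained strands/frames of the coding blocks; this recodes one
    unconstrained codon of the host block so the chance frame acquires a
    stop, without touching any planted element.
    """
    from .annotate import find_orfs

    min_aa = min(100, spec.ns1_length, spec.ns2_length, spec.vp_length)
    expected = {
        (lay.ns1_start, lay.ns1_stop[1], "+"),
        (lay.ns2_start, lay.ns2_stop[1], "+"),
        (lay.vp_stop[0], lay.vp_aug_end, "-"),
    }
    ns_cons = _ns_constraints(spec, lay)
    vp_cons = _vp_constraints(spec, lay)
    va = lay.vp_aug_end
    for _round in range(25):
        genome = NucleotideSequence(id="tmp", residues="".join(g))
        spurious = [
            o
            for o in find_orfs(genome, min_aa=min_aa)
            if (o.feature.start, o.feature.end, o.feature.strand) not in expected
        ]
        if not spurious:
            return True
        orf = spurious[0]
        s, e, strand = orf.feature.start, orf.feature.end, orf.feature.strand
        # forward-coordinate triples that are codons of the chance frame,
        # ordered middle-out so the break splits the ORF well below min_aa
        if strand == "+":
            triples = [(t, t + 2) for t in range(s + 3, e - 4, 3)]
            desired = STOP_CODONS
        else:
            triples = [(e - 3 * k - 2, e - 3 * k) for k in range(1, (e - s) // 3 - 1)]
            desired = {rc(c) for c in STOP_CODONS}
        triples.sort(key=lambda iv: abs((iv[0] + iv[1]) / 2 - (s + e) / 2))
        fixed_done = False
        for lo, hi in triples:
            for region_lo, region_hi, cons, reverse in (
                (lay.ns1_start, lay.ns1_stop[1], ns_cons, False),
                (lay.vp_stop[0], va, vp_cons, True),
            ):
                if lo < region_lo or hi > region_hi:
                    continue
                # host codon slots overlapping this triple
                if not reverse:
                    cis = {(p - region_lo) // 3 for p in (lo, hi)}
                else:
                    cis = {(region_hi - p) // 3 for p in (lo, hi)}
                for ci in sorted(cis):
                    region = _region_str(g, region_lo, region_hi, reverse)
                    current = region[3 * ci : 3 * ci + 3]
                    order = rng.permutation(len(SENSE_CODONS))
                    for oi in order:
                        cand = SENSE_CODONS[oi]
                        if cand == current or not _codon_ok(region, ci, cand, cons):
                            continue
                        _write_codon(g, region_lo, region_hi, reverse, ci, cand)
                        if "".join(g[lo - 1 : hi]) in desired:
                            fixed_done = True
                            break
                        _write_codon(g, region_lo, region_hi, reverse, ci, current)
                    if fixed_done:
                        break
                if fixed_done:
                    break
            if fixed_done:
                break
        if not fixed_done:
            return False
    return False


def _region_str(g: list[str], lo: int, hi: int, reverse: bool) -> str:
    s = "".join(g[lo - 1 : hi])
    return rc(s) if reverse else s


def _write_codon(
    g: list[str], lo: int, hi: int, reverse: bool, ci: int, codon: str
) -> None:
    if not reverse:
        base = lo - 1 + 3 * ci
        g[base : base + 3] = list(codon)
    else:
        # mRNA codon ci occupies forward positions hi-3*ci-2 .. hi-3*ci
        base = hi - 3 * ci - 3
        g[base : base + 3] = list(rc(codon))


# ---------------------------------------------------------------------------
# Genome assembly


def _rand_base(rng: np.random.Generator) -> str:
    return _BASES[rng.integers(4)]


def _scrub(
    g: list[str],
    locked: list[bool],
    rng: np.random.Generator,
    zone: tuple[int, int],
    patterns: list[str],
    allowed_starts: set[int],
) -> None:
    """Remove pattern occurrences (1-based zone) by mutating unlocked bases."""
    lo, hi = zone
    for _ in range(400):
        found = None
        for pat in patterns:
            for p in range(lo, hi + 1):
                if p in allowed_starts:
                    continue
                if p + len(pat) - 1 > len(g):
                    break
                if "".join(g[p - 1 : p + len(pat) - 1]) == pat:
                    found = (p, pat)
                    break
            if found:
                break
        if found is None:
            return
        p, pat = found
        free = [q for q in range(p, p + len(pat)) if not locked[q - 1]]
        if not free:
            raise RuntimeError(f"cannot scrub locked pattern {pat} at {p}")
        q = free[len(free) // 2]
        choices = [b for b in "ACGT" if b != g[q - 1]]
        g[q - 1] = choices[rng.integers(len(choices))]
    raise RuntimeError("pattern scrub did not converge")


def _assemble(spec: GenomeSpec, lay: _Layout, rng: np.random.Generator):
    L = lay.L
    g: list[str] = ["A"] * L
    locked = [False] * L
    free_fill: list[int] = []

    def place(motif: str, start: int) -> None:
        for k, ch in enumerate(motif):
            g[start - 1 + k] = ch
            locked[start - 1 + k] = True

    place(spec.tata_motif, lay.tata5[0])
    for a, _b in lay.g4s:
        place(G4_TRACT, a)
    for u in lay.uaugs:
        place("ATGTAA", u)
    place(spec.tata_like_motif, lay.ns_tata_like[0])
    place(spec.polya_motif, lay.ns_polya[0])
    place(rc(spec.polya_motif), lay.vp_polya[0])  # VP poly(A), minus strand
    place("TTACAT", lay.vp_uaug[0])  # leader uAUG + stop of the VP mRNA

    # terminal hairpin block [1, R]: palindromic columns except the flip-flop
    # edges and centre (unpaired bubbles that make flip and flop distinct)
    R, arm, f = lay.R, lay.arm, lay.f
    for k in range(1, arm + 1):
        m = R + 1 - k
        if locked[m - 1]:
            g[k - 1] = _COMP[g[m - 1]]
        else:
            b = _rand_base(rng)
            g[k - 1], g[m - 1] = b, _COMP[b]
        locked[k - 1] = locked[m - 1] = True
    if f:
        s0, e0 = lay.flip
        c = (R + 1) // 2
        # Bubble columns must be non-complementary AND unpairable in both
        # windows: A.G here mirrors to C.T in the 3' repeat (also unpairable).
        # The bases flanking the bubble and the loop are pinned so that no
        # alternative pairing of equal weight exists; otherwise the fold
        # optimum is tie-degenerate and the two hairpins can fold
        # asymmetrically.
        fixed_cols = {
            s0: "A", e0: "G",          # bubble
            s0 + 1: "G", e0 - 1: "C",  # inner stem ends on a strong pair
            arm: "G",                  # arm stem also ends on a strong pair
            c - 1: "A", c: "A", c + 1: "T",  # hairpin loop
            c - 2: "C", c + 2: "G",
        }
        for k, b in fixed_cols.items():
            g[k - 1] = b
            locked[k - 1] = True
        g[R - arm] = "C"  # partner of the arm-innermost column
        locked[R - arm] = True
        for k in range(s0 + 2, c - 2):
            m = R + 1 - k
            b = _rand_base(rng)
            g[k - 1], g[m - 1] = b, _COMP[b]
            locked[k - 1] = locked[m - 1] = True

    # coding blocks
    ns = _ns_region(rng, spec, lay)
    for k, ch in enumerate(ns):
        g[lay.ns1_start - 1 + k] = ch
        locked[lay.ns1_start - 1 + k] = True
    mrna = _vp_mrna(rng, spec, lay)
    vp_fw = rc(mrna)
    for k, ch in enumerate(vp_fw):
        g[lay.vp_stop[0] - 1 + k] = ch
        locked[lay.vp_stop[0] - 1 + k] = True

    # random fill everywhere still untouched, outside the 3' ITR mirror zone
    for p in range(1, L - lay.itr + 1):
        if not locked[p - 1] and g[p - 1] == "A":
            g[p - 1] = _rand_base(rng)
            free_fill.append(p)

    # guard zones: keep the NS leader free of spurious starts/promoters and
    # the poly(A) neighbourhoods unambiguous
    allowed = set(lay.uaugs)
    _scrub(
        g, locked, rng,
        (lay.R + 1, lay.ns1_start - 1),
        ["ATG", spec.tata_motif, spec.tata_like_motif],
        allowed | {lay.ns_tata_like[0]},
    )
    _scrub(
        g, locked, rng,
        (lay.vp_polya[1] + 1, lay.vp_stop[0] - 1),
        [rc(spec.polya_motif)],
        set(),
    )
    _scrub(
        g, locked, rng,
        (lay.vp_aug_end + 1, L - lay.itr),
        ["CAT"],
        {lay.vp_uaug[0] + 3},
    )

    # 3' ITR = reverse complement of the 5' ITR
    for p in range(L - lay.itr + 1, L + 1):
        g[p - 1] = _COMP[g[L - p]]

    # break the inverted repeat exactly at itr_length
    b = L - lay.itr
    forbidden = {_COMP[g[lay.itr]]}
    for cand in "GACT":
        if cand in forbidden:
            continue
        g[b - 1] = cand
        window = "".join(g[b - 4 : b + 2])
        if "CAT" not in window:
            break
    if not _repair_spurious_orfs(g, spec, lay, rng):
        return None, free_fill
    return g, free_fill


def _make_truth(spec: GenomeSpec, lay: _Layout, g: list[str]) -> SyntheticTruth:
    L = lay.L
    genome = NucleotideSequence(
        id=f"synthetic_ambidensovirus_seed{spec.seed}",
        residues="".join(g),
        description="synthetic ambisense densovirus-like genome",
    )

    def mirror(iv: tuple[int, int]) -> tuple[int, int]:
        return (L + 1 - iv[1], L + 1 - iv[0])

    F = Feature
    K = FeatureKind
    feats = [
        F(K.ITR5, 1, lay.itr, "+"),
        F(K.ITR3, L - lay.itr + 1, L, "-"),
        F(K.HAIRPIN, 1, lay.R, "+"),
        F(K.HAIRPIN, L - lay.R + 1, L, "-"),
        F(K.TATA, *lay.tata5, "+"),
        F(K.TATA, *mirror(lay.tata5), "-"),
        F(K.TATA_LIKE, *lay.ns_tata_like, "+", attributes={"role": "NS_promoter"}),
        F(K.TATA_LIKE, *lay.internal_tata_like, "-",
          attributes={"role": "internal_VP_promoter"}),
        F(K.TSS, lay.ns_tata_like[0] + 32, lay.ns_tata_like[0] + 34, "+"),
        F(K.POLYA, *lay.ns_polya, "+"),
        F(K.POLYA, *lay.vp_polya, "-"),
        F(K.ORF, lay.ns1_start, lay.ns1_stop[1], "+",
          attributes={"name": "NS1", "aa_length": str(spec.ns1_length)}),
        F(K.ORF, lay.ns2_start, lay.ns2_stop[1], "+",
          attributes={"name": "NS2", "aa_length": str(spec.ns2_length)}),
        F(K.ORF, lay.vp_stop[0], lay.vp_aug_end, "-",
          attributes={"name": "VP", "aa_length": str(spec.vp_length)}),
        F(K.ORF, lay.vp_stop[0], lay.trunc_end, "-",
          attributes={"name": "truncated_VP",
                      "aa_length": str(spec.truncated_vp_length)}),
    ]
    if lay.f:
        feats.append(F(K.FLIPFLOP, *lay.flip, "+",
                       attributes={"repeat_length": str(lay.R)}))
        feats.append(F(K.FLIPFLOP, *mirror(lay.flip), "-",
                       attributes={"repeat_length": str(lay.R)}))
    for iv in lay.g4s:
        feats.append(F(K.G4, *iv, "+"))
        feats.append(F(K.G4, *mirror(iv), "-"))
    if lay.primer_fwd is not None:
        feats.append(F(K.PRIMER_SITE, *lay.primer_fwd, "+"))
        feats.append(F(K.PRIMER_SITE, *lay.primer_rev, "-"))
    # published protein-domain coordinates shipped as a sidecar annotation
    # (domain calls are accepted from external tools, not recomputed)
    for name, a, b in (
        ("HuH", 256, 258), ("YuxK", 307, 310),
        ("SF3_helicase", 447, 652), ("Parvo_NS1", 507, 617),
    ):
        feats.append(F(K.PROTEIN_MOTIF, a, b, "+",
                       attributes={"name": name, "protein": "NS1",
                                   "coordinates": "amino_acid"}))
    for name, a, b in (("PLA2", 5, 45), ("Denso_VP4", 342, 669)):
        feats.append(F(K.PROTEIN_MOTIF, a, b, "+",
                       attributes={"name": name, "protein": "VP",
                                   "coordinates": "amino_acid"}))
    feats.sort(key=lambda x: (x.start, x.kind.value))
    return SyntheticTruth(
        genome=genome, features=feats, haplotypes=[], eve_loci=[], spec=spec
    )


def _verify(truth: SyntheticTruth, lay: _Layout, spec: GenomeSpec) -> bool:
    from .annotate import build_transcription_map, find_orfs, scan_protein_motifs
    from .epcr import PrimerPair, in_silico_pcr
    from .telomere import detect_flip_flop, detect_itr, fold_hairpin, scan_g_quadruplex

    genome = truth.genome
    it = detect_itr(genome)
    if it is None or it.length != lay.itr or it.mismatches != 0:
        return False
    ff = detect_flip_flop(genome)
    if ff.repeat_length != lay.R:
        return False
    if lay.f:
        if ff.relation != "inverted" or ff.inversion != lay.flip:
            return False
    elif ff.relation != "direct":
        return False
    min_aa = min(100, spec.ns1_length, spec.ns2_length, spec.vp_length)
    orfs = find_orfs(genome, min_aa=min_aa)
    expected = {
        (lay.ns1_start, lay.ns1_stop[1], "+"),
        (lay.ns2_start, lay.ns2_stop[1], "+"),
        (lay.vp_stop[0], lay.vp_aug_end, "-"),
    }
    got = {(o.feature.start, o.feature.end, o.strand) for o in orfs}
    if got != expected:
        return False
    tmap = build_transcription_map(genome, orfs)
    if tmap.ns_unit.promoter is None or tmap.ns_unit.promoter.start != lay.ns_tata_like[0]:
        return False
    if tmap.ns_unit.leader_uaug_count != 3 or tmap.leaky_scan.verdict != "leaky_scanning_plausible":
        return False
    if tmap.ns_unit.polya is None or tmap.ns_unit.polya.start != lay.ns_polya[0]:
        return False
    if tmap.vp_unit.promoter is None or tmap.vp_unit.leader_uaug_count != 1:
        return False
    if tmap.vp_unit.polya is None or tmap.vp_unit.polya.start != lay.vp_polya[0]:
        return False
    t = tmap.truncated_vp
    if t is None or not t.in_frame_with_vp or t.aa_length != spec.truncated_vp_length:
        return False
    if t.start_interval != (lay.trunc_end - 2, lay.trunc_end):
        return False
    s = genome.residues
    if fold_hairpin(s[: lay.R]).structure != fold_hairpin(s[-lay.R:]).structure:
        return False
    hits = scan_g_quadruplex(genome)
    for iv in lay.g4s:
        if not any(h.strand == "+" and h.start <= iv[1] and h.end >= iv[0] for h in hits):
            return False
        miv = (lay.L + 1 - iv[1], lay.L + 1 - iv[0])
        if not any(h.strand == "-" and h.start <= miv[1] and h.end >= miv[0] for h in hits):
            return False
    ns1_orf = next(o for o in orfs if o.feature.start == lay.ns1_start)
    motif_starts = {
        (f.attributes["name"], f.start)
        for f in scan_protein_motifs(ns1_orf.protein)
    }
    if ("HuH", 256) not in motif_starts or ("YuxK", 307) not in motif_starts:
        return False
    from .annotate import nickase_motif_pair

    if nickase_motif_pair(ns1_orf.protein) != (256, 307):
        return False  # the planted pair must be the first co-occurring one
    if lay.primer_fwd is not None:
        amps = in_silico_pcr(genome, PrimerPair(PRIMER_FWD, PRIMER_REV))
        if len(amps) != 1 or amps[0].length != AMPLICON_BP:
            return False
    return True


def build_ambisense_genome(spec: GenomeSpec | None = None) -> SyntheticTruth:
    """Construct a truth-annotated ambisense genome satisfying the spec.

    Raises :class:`SpecLayoutError` when the requested elements collide.
    Construction is by constrained sampling followed by verification with
    the package's own detectors; deterministic for a fixed seed.
    """
    if spec is None:
        spec = GenomeSpec()
    lay = _layout(spec)
    for attempt in range(60):
        rng = np.random.default_rng([spec.seed % (2**31), attempt])
        g, free_fill = _assemble(spec, lay, rng)
        if g is None:
            continue
        truth = _make_truth(spec, lay, g)
        if not _verify(truth, lay, spec):
            continue
        if spec.haplotype_snps:
            pool = [p for p in free_fill if lay.itr < p <= lay.L - lay.itr]
            picks = rng.choice(len(pool), size=min(spec.haplotype_snps, len(pool)),
                               replace=False)
            for idx in sorted(picks):
                p = pool[idx]
                ref = truth.genome.residues[p - 1]
                alts = [b for b in "ACGT" if b != ref]
                alt = alts[rng.integers(3)]
                truth.haplotypes.append((p, ref, alt, spec.haplotype_freq))
        return truth
    raise RuntimeError(
        "could not realise the genome spec after 60 attempts; "
        "the requested element layout is likely infeasible"
    )


# ---------------------------------------------------------------------------
# Read simulation


def simulate_rca_reads(
    truth: SyntheticTruth,
    params: ReadSimParams,
    host: NucleotideSequence | None = None,
) -> list[NucleotideSequence]:
    """Simulate 150 nt (by default) reads with terminal coverage decay.

    Reads are drawn from both genome strands (each read's orientation is
    random, as both strands are packaged by homotelomeric parvoviruses),
    with start-position weight ``terminal_decay`` for reads overlapping
    either ITR.  Haplotype alternates are emitted per site at their stated
    frequencies; substitution errors are i.i.d.  Deterministic per seed.
    """
    g = truth.genome.residues
    L = len(g)
    rl = params.read_length
    if rl > L:
        raise ValueError(f"read_length {rl} exceeds genome length {L}")
    if params.host_fraction > 0 and host is None:
        raise ValueError("host sequence required when host_fraction > 0")
    rng = np.random.default_rng(params.seed)
    # virtual starts may precede position 1: a linear genome is fragmented,
    # so reads end exactly at the termini (clipped to >= 30 nt)
    min_clip = min(30, rl)
    starts = np.arange(-(rl - min_clip), L - min_clip + 1)
    n_total = max(1, int(round(params.mean_depth * len(starts) / rl)))
    n_host = int(round(params.host_fraction * n_total))
    n_viral = n_total - n_host
    itr = truth.spec.itr_length
    a = np.maximum(starts, 0)
    b = np.minimum(starts + rl, L) - 1
    w = np.ones(len(starts), dtype=float)
    w[(a < itr) | (b >= L - itr)] = params.terminal_decay
    p = w / w.sum()
    reads: list[NucleotideSequence] = []

    def finish(seq: str, origin: str, pos: int, idx: int, mate: str = "") -> None:
        arr = np.frombuffer(seq.encode(), dtype="S1").astype("U1")
        if params.substitution_rate > 0:
            mask = rng.random(len(arr)) < params.substitution_rate
            for i in np.nonzero(mask)[0]:
                choices = [b for b in "ACGT" if b != arr[i]]
                arr[i] = choices[rng.integers(3)]
        seq = "".join(arr)
        flip = bool(rng.integers(2))
        if flip:
            seq = rc(seq)
        reads.append(
            NucleotideSequence(
                id=f"sim{idx:06d}{mate}",
                residues=seq,
                quality="I" * len(seq),
                description=f"origin={origin} pos={pos} rc={int(flip)}",
            )
        )

    def apply_haplotypes(seq: str, start0: int) -> str:
        if not truth.haplotypes:
            return seq
        chars = list(seq)
        for pos, _ref, alt, freq in truth.haplotypes:
            i = pos - 1 - start0
            if 0 <= i < len(chars) and rng.random() < freq:
                chars[i] = alt
        return "".join(chars)

    idx = 0
    if params.paired:
        n_frag = (n_viral + 1) // 2
        for _ in range(n_frag):
            st = int(rng.choice(starts, p=p))
            insert = int(
                max(rl, round(rng.normal(params.insert_mean, params.insert_sd)))
            )
            lo, hi = max(0, st), min(L, st + insert)
            if hi - lo < rl:
                hi = min(L, lo + rl)
                lo = max(0, hi - rl)
            frag = apply_haplotypes(g[lo:hi], lo)
            finish(frag[:rl], "viral", lo + 1, idx, "/1")
            finish(rc(frag[-rl:]), "viral", hi - rl + 1, idx, "/2")
            idx += 1
    else:
        for _ in range(n_viral):
            st = int(rng.choice(starts, p=p))
            lo, hi = max(0, st), min(L, st + rl)
            finish(apply_haplotypes(g[lo:hi], lo), "viral", lo + 1, idx)
            idx += 1
    if n_host:
        h = host.residues
        if len(h) < rl:
            raise ValueError("host shorter than the read length")
        for _ in range(n_host):
            st = int(rng.integers(len(h) - rl + 1))
            finish(h[st : st + rl], "host", st + 1, idx)
            idx += 1
    return reads


# ---------------------------------------------------------------------------
# Hosts and endogenous viral elements


def random_host(length: int = 20000, seed: int = 0, ident: str = "host_scaffold_1") -> NucleotideSequence:
    """A uniform-random host scaffold (synthetic stand-in for a real assembly)."""
    rng = np.random.default_rng(seed)
    return NucleotideSequence(
        id=ident,
        residues="".join(_BASES[rng.integers(4, size=length)]),
        description="synthetic host scaffold",
    )


def _mutate_to_identity(
    s: str,
    identity: float,
    rng: np.random.Generator,
    locked: set[int] | None = None,
    frame_nostop: tuple[int, int, int] | None = None,
) -> str:
    """Substitute round((1-identity)*len) positions, avoiding locked ones.

    ``frame_nostop`` = (frame_start, lo, hi): 0-based codon frame anchor and
    inclusive bounds of a window that must remain free of in-frame stops.
    """
    chars = list(s)
    n_sub = int(round((1.0 - identity) * len(s)))
    candidates = [i for i in range(len(s)) if not locked or i not in locked]
    order = rng.permutation(len(candidates))
    done = 0
    for oi in order:
        if done >= n_sub:
            break
        i = candidates[oi]
        old = chars[i]
        alts = [b for b in "ACGT" if b != old]
        rng.shuffle(alts)
        for alt in alts:
            chars[i] = alt
            if frame_nostop is not None:
                f0, lo, hi = frame_nostop
                cs = i - (i - f0) % 3
                codon = "".join(chars[cs : cs + 3])
                if lo <= cs and cs + 2 <= hi and codon in STOP_CODONS:
                    chars[i] = old
                    continue
            done += 1
            break
    return "".join(chars)


def _scrub_dinucleotide(chars: list[str], lo: int, hi: int, locked: set[int]) -> None:
    """Remove AG dinucleotides within [lo, hi] (0-based incl.), respecting locks."""
    for i in range(lo, hi):
        if chars[i] == "A" and chars[i + 1] == "G":
            if i + 1 not in locked:
                chars[i + 1] = "C"
            elif i not in locked:
                chars[i] = "C"


def plant_eve_locus(
    host: NucleotideSequence,
    truth: SyntheticTruth,
    viral_interval: tuple[int, int],
    identity: float = 0.75,
    copies: int = 1,
    intron: tuple[int, str, str] | None = None,
    seed: int = 0,
    insert_at: int | None = None,
) -> tuple[NucleotideSequence, SyntheticTruth]:
    """Insert head-to-tail copies of a viral interval into a host scaffold.

    Returns the modified host and the truth object with the locus recorded.
    The copies are verbatim repeats of one mutated unit, so the planted
    identity to the viral genome is exact by construction.  When planting
    several loci on one scaffold, plant left to right (coordinates of
    earlier loci are not shifted).
    """
    if not 0.5 <= identity <= 1.0:
        raise ValueError("identity must be in [0.5, 1.0]")
    if copies < 1:
        raise ValueError("copies must be >= 1")
    a, b = viral_interval
    v = truth.genome.slice(a, b)  # raises on out-of-bounds
    rng = np.random.default_rng(seed % (2**31))
    unit = _mutate_to_identity(v, identity, rng)
    intron_iv = None
    if intron is not None:
        ilen, donor, acceptor = intron
        if ilen < 4:
            raise ValueError("intron too short for donor/acceptor sites")
        mid = len(unit) // 2
        interior = "".join(_BASES[rng.integers(4, size=ilen - 4)])
        ichars = list(donor + interior + acceptor)
        _scrub_dinucleotide(ichars, 0, ilen - 3, {0, 1, ilen - 2, ilen - 1})
        iseq = "".join(ichars)
        unit = unit[:mid] + iseq + unit[mid:]
        intron_off = mid
    segment = unit * copies
    k = insert_at if insert_at is not None else len(host.residues) // 2
    new_res = host.residues[:k] + segment + host.residues[k:]
    start = k + 1
    if intron is not None:
        intron_iv = (start + intron_off, start + intron_off + intron[0] - 1)
    locus = EveLocus(
        scaffold=host.id,
        start=start,
        end=k + len(segment),
        viral_interval=viral_interval,
        identity=identity,
        copies=copies,
        unit_length=len(unit),
        intron=intron_iv,
    )
    new_truth = dataclasses.replace(truth, eve_loci=truth.eve_loci + [locus])
    new_host = NucleotideSequence(
        id=host.id, residues=new_res, description=host.description
    )
    return new_host, new_truth


def build_rep_fusion_locus(
    truth: SyntheticTruth,
    identity: float = 0.75,
    intron_length: int = 1271,
    fusion_aa: int = 486,
    seed: int = 0,
    scaffold_id: str = "host_chr10_like",
) -> tuple[NucleotideSequence, dict]:
    """Synthetic host locus with the architecture of a Rep-HTH fusion EVE.

    A degraded viral integrant (near-complete 5' ITR plus half the NS
    transcription unit) retains the NS1 reading frame up to a GT splice
    donor; a downstream host exon supplies, past an AG acceptor, the
    C-terminal DNA-binding domain, yielding a spliced fusion ORF of
    ``fusion_aa`` amino acids over a ``intron_length`` nt GT..AG intron.
    Returns the scaffold and a dict of planted coordinates.
    """
    lay = _layout(truth.spec)
    rng = np.random.default_rng(seed % (2**31))
    vs = 41
    ve = lay.ns2_stop[0] - 35  # integrant ends 34 nt before the NS2 stop
    donor_v = lay.ns1_start + 1030  # first intron base; exon1 ends one nt before
    if donor_v + 5 > ve:
        raise SpecLayoutError("NS unit too short for the fusion-locus blueprint")
    v = truth.genome.slice(vs, ve)
    r = lambda p: p - vs  # genome coord -> 0-based integrant offset
    locked = {r(lay.ns1_start), r(lay.ns1_start) + 1, r(lay.ns1_start) + 2,
              r(donor_v), r(donor_v) + 1}
    chars = list(
        _mutate_to_identity(
            v, identity, rng, locked=locked,
            frame_nostop=(r(lay.ns1_start), r(lay.ns1_start), r(donor_v) - 1),
        )
    )
    chars[r(donor_v)], chars[r(donor_v) + 1] = "G", "T"
    # in-frame stop at the first codon boundary past the donor: candidates
    # splicing at later donors cannot cross the junction
    anchor = r(lay.ns1_start)
    stop_at = r(donor_v) + 2
    stop_at += (3 - (stop_at - anchor) % 3) % 3
    chars[stop_at : stop_at + 3] = list("TAA")
    locked |= {stop_at, stop_at + 1, stop_at + 2}
    # no competing acceptors inside the viral part of the intron
    _scrub_dinucleotide(chars, r(donor_v), len(chars) - 1, locked)
    # scrub in-frame leader ATGs so the fusion ORF starts at the NS1 AUG
    for i in range(r(lay.ns1_start) % 3, r(lay.ns1_start) - 2, 3):
        if "".join(chars[i : i + 3]) == "ATG":
            chars[i + 2] = "A"
    vmut = "".join(chars)

    exon1_codons = (donor_v - lay.ns1_start) // 3  # 343 at the default layout
    extra = (donor_v - lay.ns1_start) % 3  # exon1 nt past the last full codon
    host_exon_codons = fusion_aa - exon1_codons - (1 if extra else 0)
    if host_exon_codons < 1:
        raise SpecLayoutError("fusion_aa too small for the exon1 length")
    junction = "CC"[: (3 - extra) % 3]
    # host exon body with periodic cross-frame stop blocks: translations
    # entering the exon out of frame (via a competing acceptor) terminate
    # within a few codons instead of reading through
    block = ["TTA", "ATA", "GCT", "AAA"]  # stops in both shifted frames
    codons: list[str] = []
    while len(codons) < host_exon_codons:
        if len(codons) % 8 == 0 and len(codons) + 4 <= host_exon_codons:
            codons.extend(block)
        else:
            codons.append(SENSE_CODONS[int(rng.integers(len(SENSE_CODONS)))])
    body = "".join(codons[:host_exon_codons])
    exon2 = junction + body + "TAA"
    host_intron_len = intron_length - (ve - donor_v + 1) - 2
    if host_intron_len < 0:
        raise SpecLayoutError("intron_length shorter than the viral intron part")
    # intron interior interleaved with all-frame stop blocks so no
    # translation entering it (from any competing junction) can run far
    iparts = []
    while sum(len(p) for p in iparts) < host_intron_len:
        iparts.append("TTAATTAATTAA")
        iparts.append("".join(_BASES[rng.integers(4, size=24)]))
    hchars = list("".join(iparts)[:host_intron_len])
    _scrub_dinucleotide(hchars, 0, len(hchars) - 2, set())
    if hchars and hchars[-1] == "A":  # avoid AG across the intron/acceptor join
        hchars[-1] = "C"
    host5 = "".join(_BASES[rng.integers(4, size=600)])
    # downstream host tail interleaved with all-frame stop blocks: no
    # reading frame can run far past the planted terminator, so competing
    # splice candidates cannot outgrow the planted fusion ORF
    parts = []
    while sum(len(p) for p in parts) < 400:
        parts.append("TTAATTAATTAA")
        parts.append("".join(_BASES[rng.integers(4, size=18)]))
    host3 = "".join(parts)[:400]
    residues = host5 + vmut + "".join(hchars) + "AG" + exon2 + host3
    scaffold = NucleotideSequence(
        id=scaffold_id,
        residues=residues,
        description="synthetic host scaffold with a planted Rep-fusion EVE",
    )
    donor_s = 600 + r(donor_v) + 1
    acceptor_s = 600 + len(vmut) + host_intron_len + 2
    info = {
        "eve_interval": (601, 600 + len(vmut)),
        "viral_interval": (vs, ve),
        "start_codon": 600 + r(lay.ns1_start) + 1,
        "donor": donor_s,
        "acceptor": acceptor_s,
        "intron_length": acceptor_s - donor_s + 1,
        "fusion_aa": fusion_aa,
    }
    assert info["intron_length"] == intron_length
    return scaffold, info


# ---------------------------------------------------------------------------
# Output


def write_truth(truth: SyntheticTruth, outdir: str | Path) -> dict[str, Path]:
    """Write genome FASTA, truth GFF3 and truth JSON to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "genome.fasta",
        "gff3": outdir / "truth.gff3",
        "json": outdir / "truth.json",
    }
    write_fasta([truth.genome], paths["fasta"])
    write_features(truth.features, truth.genome, paths["gff3"])
    payload = {
        "spec": asdict(truth.spec),
        "haplotypes": truth.haplotypes,
        "eve_loci": [asdict(e) for e in truth.eve_loci],
    }
    paths["json"].write_text(json.dumps(payload, indent=2))
    return paths
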