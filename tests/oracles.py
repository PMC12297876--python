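"""Independent oracles shared by the unit and acceptance suites.

Each oracle recomputes a quantity by a different route than the
implementation under test: explicit enumeration, brute force, or an
established third-party implementation.
"""

import re

import numpy as np
from Bio import Align

from ambidense.core import STOP_CODONS, rc
from ambidense.simulate import GenomeSpec, SpecLayoutError, _layout
from ambidense.telomere import MIN_LOOP, PAIR_WEIGHTS, qgrs_score

BASES = "ACGT"


def dna(rng, n):
    return "".join(BASES[i] for i in rng.integers(4, size=n))


# --- hairpin folding: explicit enumeration of all nested structures --------


def enumerate_structures(s):
    def helper(i, j):
        if j - i < MIN_LOOP + 1:
            yield frozenset()
            return
        for rest in helper(i + 1, j):
            yield rest
        for k in range(i + MIN_LOOP + 1, j + 1):
            if PAIR_WEIGHTS.get((s[i], s[k]), 0) > 0:
                for inner in helper(i + 1, k - 1):
                    for outer in helper(k + 1, j):
                        yield inner | outer | {(i, k)}

    return helper(0, len(s) - 1)


def best_enumerated_score(s):
    best = 0
    for struct in enumerate_structures(s):
        score = sum(PAIR_WEIGHTS[(s[i], s[j])] for i, j in struct)
        best = max(best, score)
    return best


# --- G4: regex-driven enumeration with the shared scoring -------------------


def brute_g4(s, min_run=2, max_length=45):
    cands = []
    for x in range(min_run, 13):
        starts = [m.start() for m in re.finditer(f"(?=G{{{x}}})", s)]
        for a in starts:
            for b in (p for p in starts if a + x <= p <= a + x + 36):
                for c in (p for p in starts if b + x <= p <= b + x + 36):
                    for d in (p for p in starts if c + x <= p <= c + x + 36):
                        if d + x - a <= max_length:
                            cands.append(
                                (a, d + x - 1, x, (b - a - x, c - b - x, d - c - x))
                            )
    scored = sorted(
        cands, key=lambda t: (-qgrs_score(t[2], t[3]), t[0], t[1] - t[0])
    )
    kept = []
    for a, b, x, loops in scored:
        if all(b < ka or a > kb for ka, kb, *_ in kept):
            kept.append((a, b, x, loops))
    return kept


# --- ORFs: six-frame enumeration -------------------------------------------


def brute_orfs(s, min_aa):
    out = set()
    L = len(s)
    for strand in "+-":
        t = s if strand == "+" else rc(s)
        for frame in range(3):
            start = None
            for i in range(frame, len(t) - 2, 3):
                codon = t[i : i + 3]
                if codon in STOP_CODONS:
                    if start is not None and (i - start) // 3 >= min_aa:
                        if strand == "+":
                            out.add((start + 1, i + 3, "+"))
                        else:
                            out.add((L - i - 2, L - start, "-"))
                    start = None
                elif codon == "ATG" and start is None:
                    start = i
    return out


# --- local alignment: Biopython full dynamic program ------------------------


def biopython_local_score(a, b):
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -7
    aligner.extend_gap_score = -2
    return max(aligner.score(a, b), aligner.score(rc(a), b))


# --- random valid genome specs ----------------------------------------------


def random_valid_spec(rng) -> GenomeSpec:
    """Draw a feasible GenomeSpec with a realistic telomere geometry.

    Every palindromic column run of the hairpin (the arms, and the two
    interior halves of the flip-flop) is kept shorter than the 30 nt
    read-mapping anchor, as in the natural geometry (arm 26, half-run 25):
    longer pure-palindromic runs admit mismatch-free mirror-register read
    placements, making terminal assembly formally unidentifiable from
    short reads.
    """
    for _ in range(50):
        ns1 = int(rng.integers(450, 720))
        vp = int(rng.integers(600, 750))
        arm = int(rng.integers(16, 30))
        f = 2 * int(rng.integers(10, 31)) + 1  # odd, 21..61
        R = 2 * arm + f
        itr = int(rng.integers(max(150, R + 28), 251))
        spec = GenomeSpec(
            total_length=int(rng.integers(4700, 5600)),
            itr_length=itr,
            terminal_repeat_length=R,
            flipflop_length=f,
            ns1_length=ns1,
            ns2_length=int(rng.integers(150, ns1 - 70)),
            vp_length=vp,
            truncated_vp_length=int(rng.integers(150, vp - 140)),
            seed=int(rng.integers(2**16)),
        )
        try:
            _layout(spec)
            return spec
        except SpecLayoutError:
            continue
    raise AssertionError("could not draw a valid spec")
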