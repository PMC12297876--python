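"""Telomere analysis: ITRs, flip-flop terminal repeats, hairpin folds, G4s.

Parvoviral telomeres are inverted terminal repeats (ITRs) whose outermost
segment folds back on itself into a hairpin.  In homotelomeric ambisense
densoviruses the two terminal hairpin regions are imperfect *direct* repeats
of each other that differ by an internal segment inversion (the "flip-flop"
palindrome), so both termini fold into the same structure.

A consequence worth keeping in mind throughout this module: if the ITR is a
perfect inverted repeat, the 3'-terminal window is exactly the reverse
complement of the 5'-terminal window.  Direct-matching columns between the
two windows are then precisely the self-complementary (palindromic) columns
of the 5' window, and the flip-flop inversion is detectable as the centred
block of non-palindromic columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import NucleotideSequence, rc

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

#: base-pair weights for the hairpin fold (G-C strongest, G-T wobble weakest)
PAIR_WEIGHTS = {
    ("G", "C"): 3, ("C", "G"): 3,
    ("A", "T"): 2, ("T", "A"): 2,
    ("G", "T"): 1, ("T", "G"): 1,
}
MIN_LOOP = 3


@dataclass
class ItrResult:
    length: int
    mismatches: int
    left: tuple[int, int]
    right: tuple[int, int]


@dataclass
class FlipFlopResult:
    repeat_length: int
    inversion: tuple[int, int] | None  # 1-based within the terminal repeat
    flank_identity: float
    relation: str  # "inverted" or "direct"

    @property
    def inversion_length(self) -> int:
        if self.inversion is None:
            return 0
        return self.inversion[1] - self.inversion[0] + 1


@dataclass
class HairpinFold:
    structure: str  # dot-bracket
    paired_bases: int
    loop_positions: list[tuple[int, int]]  # 1-based runs of hairpin-loop bases
    score: int  # weighted pair sum (energy proxy)


@dataclass
class G4Hit:
    start: int
    end: int
    strand: str
    g_run_length: int
    loops: tuple[int, int, int]
    qgrs_score: int


# ---------------------------------------------------------------------------
# ITR detection


def detect_itr(
    genome: NucleotideSequence,
    max_mismatch: int = 0,
    min_length: int = 50,
) -> ItrResult | None:
    """Maximal n such that the length-n prefix and the reverse complement of
    the length-n suffix differ at no more than ``max_mismatch`` positions."""
    s = genome.residues
    L = len(s)
    if L < 2 * min_length:
        return None
    best = 0
    mism = 0
    mism_at_best = 0
    for i in range(L // 2):
        if s[i] != _COMP.get(s[L - 1 - i], "N") or s[i] == "N":
            mism += 1
            if mism > max_mismatch:
                break
        best = i + 1
        mism_at_best = mism
    if best < min_length:
        return None
    return ItrResult(
        length=best,
        mismatches=mism_at_best,
        left=(1, best),
        right=(L - best + 1, L),
    )


# ---------------------------------------------------------------------------
# Flip-flop terminal repeats


def _window_result(D: str, E: str) -> FlipFlopResult | None:
    """Compare terminal windows as direct repeats and extract the centred
    inversion; returns None when the window shape is implausible."""
    w = len(D)
    mismatch_cols = [k for k in range(1, w + 1) if D[k - 1] != E[k - 1]]
    if not mismatch_cols:
        return FlipFlopResult(w, None, 1.0, "direct")
    lo, hi = mismatch_cols[0], mismatch_cols[-1]
    t = min(lo, w + 1 - hi)
    # the inversion must be strictly inside the repeat, with enough
    # directly matching flank columns (>= 12 per side, i.e. the shortest
    # plausible hairpin arm) to rule out spuriously shifted windows
    if t - 1 < 12:
        return None
    s0, e0 = t, w + 1 - t
    # the 5' copy of the inverted segment must match the reverse complement
    # of the 3' copy
    seg5 = D[s0 - 1 : e0]
    seg3 = E[s0 - 1 : e0]
    inv_matches = sum(a == b for a, b in zip(seg5, rc(seg3)))
    if inv_matches / len(seg5) < 0.9:
        return None
    flank_cols = [k for k in range(1, w + 1) if k < s0 or k > e0]
    flank_ident = (
        sum(D[k - 1] == E[k - 1] for k in flank_cols) / len(flank_cols)
        if flank_cols
        else 1.0
    )
    if flank_ident < 0.9:
        return None
    return FlipFlopResult(w, (s0, e0), flank_ident, "inverted")


def detect_flip_flop(
    genome: NucleotideSequence,
    repeat_length: int | str = "auto",
) -> FlipFlopResult:
    """Detect terminal direct repeats differing by an internal inversion.

    The 5'-terminal window is compared column-wise with the 3'-terminal
    window; the inversion is the minimal centred segment covering all
    directly mismatching columns, validated by requiring that the segment's
    5' copy equal the reverse complement of its 3' copy and that the flanks
    match directly (>= 90% identity).  In ``auto`` mode repeat lengths
    50..300 are searched and the best-supported window is returned.
    """
    s = genome.residues
    L = len(s)
    if repeat_length != "auto":
        w = int(repeat_length)
        if L < 2 * w:
            raise ValueError("genome shorter than twice the repeat length")
        res = _window_result(s[:w], s[-w:])
        return res if res is not None else FlipFlopResult(w, None, 0.0, "direct")
    best: FlipFlopResult | None = None
    best_key = (-1.0, -1)
    for w in range(50, min(300, L // 2) + 1):
        res = _window_result(s[:w], s[-w:])
        if res is None:
            continue
        D, E = s[:w], s[-w:]
        direct = sum(a == b for a, b in zip(D, E))
        key = (direct + (res.inversion_length if res.inversion else 0), w)
        if key > best_key:
            best_key, best = key, res
    if best is None:
        return FlipFlopResult(0, None, 0.0, "direct")
    return best


# ---------------------------------------------------------------------------
# Hairpin folding (maximum-weight nested pairing)


def _pair_weight(a: str, b: str) -> int:
    return PAIR_WEIGHTS.get((a, b), 0)


def fold_hairpin(seq: NucleotideSequence | str) -> HairpinFold:
    """Maximum-weight nested secondary structure by dynamic programming.

    Pair weights G·C=3, A·T=2, G·T=1; hairpin loops of at least three
    unpaired bases.  This is a topology/symmetry tool, not a thermodynamic
    model: scores are weighted pair counts, not free energies.  Traceback is
    deterministic (pairing the left endpoint is preferred over leaving it
    unpaired; on ties the nearest partner wins).
    """
    s = seq.residues if isinstance(seq, NucleotideSequence) else seq
    n = len(s)
    if not (1 <= n <= 500):
        raise ValueError("fold_hairpin accepts sequences of 1..500 nt")
    # weight matrix for vectorized inner maximisation
    wmat = np.zeros((n, n), dtype=np.int32)
    for i in range(n):
        for j in range(i + MIN_LOOP + 1, n):
            wmat[i, j] = _pair_weight(s[i], s[j])
    W = np.zeros((n + 1, n + 1), dtype=np.int32)  # W[i,j] over s[i..j-1], py idx

    def cell(i: int, j: int) -> int:  # inclusive python indices
        return W[i, j + 1]

    for span in range(MIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = W[i + 1, j + 1]  # i unpaired
            ks = np.arange(i + MIN_LOOP + 1, j + 1)
            if len(ks):
                # pair (i,k): w(i,k) + W(i+1,k-1) + W(k+1,j)
                vals = wmat[i, ks] + W[i + 1, ks] + W[ks + 1, j + 1]
                vals = np.where(wmat[i, ks] > 0, vals, -1)
                m = int(vals.max())
                if m > best:
                    best = m
            W[i, j + 1] = best
    # traceback
    structure = ["."] * n
    pairs: list[tuple[int, int]] = []
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j:
            continue
        target = W[i, j + 1]
        if target == 0:
            continue
        paired = False
        for k in range(i + MIN_LOOP + 1, j + 1):
            w = wmat[i, k]
            if w and w + W[i + 1, k] + W[k + 1, j + 1] == target:
                pairs.append((i, k))
                structure[i], structure[k] = "(", ")"
                stack.append((k + 1, j))
                stack.append((i + 1, k - 1))
                paired = True
                break
        if not paired:
            stack.append((i + 1, j))
    score = sum(_pair_weight(s[i], s[j]) for i, j in pairs)
    loops: list[tuple[int, int]] = []
    inner = {i: j for i, j in pairs}
    for i, j in sorted(pairs):
        if all(structure[k] == "." for k in range(i + 1, j)):
            loops.append((i + 2, j))  # 1-based run of unpaired loop bases
    return HairpinFold(
        structure="".join(structure),
        paired_bases=2 * len(pairs),
        loop_positions=loops,
        score=score,
    )


# ---------------------------------------------------------------------------
# G-quadruplex scan (QGRS-style)


def qgrs_score(run: int, loops: tuple[int, int, int]) -> int:
    """QGRS-style score: longer G-runs, shorter and more equal loops win."""
    base = 20 * (run - 2)
    balance = max(0, 18 - (max(loops) - min(loops)))
    compact = max(0, 18 - sum(loops) // 6)
    return base + balance + compact


def _g4_candidates(s: str, min_run: int, max_length: int):
    """All quadruplets of equal-length G-runs within the length bound."""
    from bisect import bisect_left, bisect_right

    n = len(s)
    # start positions of a G-run of length >= x (any offset within a longer
    # run is an admissible sub-run)
    for x in range(min_run, 13):
        starts = [
            i
            for i in range(n - x + 1)
            if all(s[i + d] == "G" for d in range(x))
        ]
        if len(starts) < 4:
            continue

        def window(prev: int) -> list[int]:
            lo = bisect_left(starts, prev + x)
            hi = bisect_right(starts, prev + x + 36)
            return starts[lo:hi]

        for a in starts:
            for b in window(a):
                for c in window(b):
                    for d in window(c):
                        if d + x - a > max_length:
                            break
                        yield (a, d + x - 1, x, (b - a - x, c - b - x, d - c - x))


def scan_g_quadruplex(
    seq: NucleotideSequence,
    min_run: int = 2,
    max_length: int = 45,
) -> list[G4Hit]:
    """Enumerate G-run quadruplets on both strands; overlapping candidates
    are reduced to the highest-scoring hit per locus and strand."""
    hits: list[G4Hit] = []
    L = len(seq.residues)
    for strand, s in (("+", seq.residues), ("-", rc(seq.residues))):
        cands = []
        for a, b, x, loops in _g4_candidates(s, min_run, max_length):
            score = qgrs_score(x, loops)
            if strand == "+":
                start, end = a + 1, b + 1
            else:
                start, end = L - b, L - a
            cands.append(G4Hit(start, end, strand, x, loops, score))
        cands.sort(key=lambda h: (-h.qgrs_score, h.start, h.end - h.start))
        kept: list[G4Hit] = []
        for h in cands:
            if all(h.end < k.start or h.start > k.end for k in kept):
                kept.append(h)
        hits.extend(kept)
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits
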