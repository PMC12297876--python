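"""Iterative contig completion from terminal-overhang reads.

A near-complete viral contig assembled from short reads typically lacks its
telomeric termini (coverage is lowest there and hairpins confuse
assemblers).  Reads that align to a contig end with bases hanging past it
carry the missing sequence; stacking those overhangs column by column and
taking a strict majority consensus extends the contig outward.  Iterating
mapping and extension until no column has enough support completes the
genome; a final re-map validates the consensus.

The read model is substitution-only (mapping is exact-seed plus ungapped
extension with a mismatch budget), which matches the simulator's error
model and keeps the column consensus well-defined.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .core import NucleotideSequence, rc


@dataclass
class ReadAlignment:
    read_id: str
    contig_start: int  # 1-based inclusive
    contig_end: int
    read_start: int  # on the oriented read, 1-based
    read_end: int
    strand: str
    mismatches: int
    left_overhang: str = ""  # oriented-read bases hanging past the contig start
    right_overhang: str = ""
    primary: bool = True  # False for equally good alternate placements


@dataclass
class ReadPile:
    contig: NucleotideSequence
    alignments: list[ReadAlignment]
    depth: np.ndarray  # per-base coverage, index 0 = contig position 1
    mismatch_profile: np.ndarray | None = None


@dataclass
class CompletionRound:
    round: int
    left_extension: int
    right_extension: int
    mapped_reads: int
    contig_length: int


@dataclass
class CompletionResult:
    genome: NucleotideSequence
    rounds: list[CompletionRound]
    status: str  # COMPLETE or PARTIAL
    pile: ReadPile


def map_reads(
    contig: NucleotideSequence,
    reads: list[NucleotideSequence],
    min_anchor: int = 30,
    max_mismatch_rate: float = 0.05,
    seed_k: int = 15,
) -> ReadPile:
    """Place each read (or its reverse complement) on the contig.

    Placement is by exact seed (``seed_k``-mers at several read offsets)
    followed by ungapped extension over the read-contig overlap; the best
    placement (fewest mismatches, then leftmost coordinate, then plus
    strand) is kept when the overlap is at least ``min_anchor`` with a
    mismatch rate within budget.  Reads may hang off either contig end;
    the hanging bases are recorded as overhang strings.
    """
    c = contig.residues
    n = len(c)
    if n < seed_k:
        raise ValueError(f"contig ({n} nt) shorter than the seed length {seed_k}")
    index: dict[str, list[int]] = {}
    for i in range(n - seed_k + 1):
        index.setdefault(c[i : i + seed_k], []).append(i)

    alignments: list[ReadAlignment] = []
    depth = np.zeros(n, dtype=np.int32)
    mism_profile = np.zeros(n, dtype=np.int32)
    for read in reads:
        cands = []  # (mismatches, offset, strand, oriented residues, ov)
        for strand, oread in (("+", read.residues), ("-", rc(read.residues))):
            m = len(oread)
            offsets_seen = set()
            seed_offsets = list(range(0, m - seed_k + 1, seed_k)) or [0]
            for so in seed_offsets:
                for p in index.get(oread[so : so + seed_k], ()):
                    off = p - so  # contig 0-based coord of read base 0
                    if off in offsets_seen:
                        continue
                    offsets_seen.add(off)
                    ov_read = max(0, -off)
                    ov_len = min(m - ov_read, n - max(0, off))
                    if ov_len < min_anchor:
                        continue
                    budget = int(max_mismatch_rate * ov_len)
                    mm = 0
                    cs = max(0, off)
                    for k in range(ov_len):
                        if oread[ov_read + k] != c[cs + k]:
                            mm += 1
                            if mm > budget:
                                break
                    if mm > budget:
                        continue
                    cands.append((mm, off, strand, oread, ov_read, ov_len))
        if not cands:
            continue
        cands.sort(key=lambda t: (t[0], t[1], t[2]))
        best = cands[0]
        # equally good alternate placements are kept as secondary records:
        # inside a palindromic telomere a read supports both termini, and
        # dropping one starves that end of coverage and overhang evidence
        chosen = [(best, True)]
        seen_off = {best[1]}
        for alt in cands[1:]:
            if alt[0] != best[0] or len(chosen) > 4:
                break
            if alt[1] in seen_off:
                continue
            seen_off.add(alt[1])
            chosen.append((alt, False))
        for (mm, off, strand, oread, ov_read, ov_len), primary in chosen:
            cs = max(0, off)
            aln = ReadAlignment(
                read_id=read.id,
                contig_start=cs + 1,
                contig_end=cs + ov_len,
                read_start=ov_read + 1,
                read_end=ov_read + ov_len,
                strand=strand,
                mismatches=mm,
                left_overhang=oread[:ov_read] if off < 0 else "",
                right_overhang=(
                    oread[ov_read + ov_len :] if off + len(oread) > n else ""
                ),
                primary=primary,
            )
            alignments.append(aln)
            depth[cs : cs + ov_len] += 1
            for k in range(ov_len):
                if oread[ov_read + k] != c[cs + k]:
                    mism_profile[cs + k] += 1
    return ReadPile(contig=contig, alignments=alignments, depth=depth,
                    mismatch_profile=mism_profile)


def extend_terminus(
    pile: ReadPile,
    end: str,
    min_support: int = 3,
    majority: float = 0.8,
) -> tuple[NucleotideSequence, int]:
    """Column-consensus extension of one contig end from overhanging reads.

    Moving outward from the contig end, a column's consensus base is
    adopted iff at least ``min_support`` overhangs cover it and the modal
    base frequency is at least ``majority``; the first failing column stops
    the extension.  Ambiguous columns therefore stop the walk rather than
    emitting ambiguity codes — hairpin arms attract mirrored reads and a
    hard stop fails safe.

    Only alignments with mismatch-free anchors contribute overhangs: a
    read mis-placed on the mirror register of a quasi-palindromic hairpin
    always mismatches its anchor at a flip-flop column, so this filter
    excludes exactly the reads whose overhangs would carry the wrong
    (flop) orientation.
    """
    if end not in ("left", "right"):
        raise ValueError("end must be 'left' or 'right'")
    overhangs = [
        a.left_overhang if end == "left" else a.right_overhang
        for a in pile.alignments
        if a.mismatches == 0
    ]
    overhangs = [o for o in overhangs if o]
    ext: list[str] = []
    col = 1
    while True:
        bases = []
        for o in overhangs:
            if len(o) >= col:
                bases.append(o[-col] if end == "left" else o[col - 1])
        if len(bases) < min_support:
            break
        counts = Counter(bases)
        base, cnt = max(counts.items(), key=lambda kv: (kv[1], kv[0]))
        if cnt / len(bases) < majority:
            break
        ext.append(base)
        col += 1
    if not ext:
        return pile.contig, 0
    if end == "left":
        new = "".join(reversed(ext)) + pile.contig.residues
    else:
        new = pile.contig.residues + "".join(ext)
    return (
        NucleotideSequence(
            id=pile.contig.id, residues=new, description=pile.contig.description
        ),
        len(ext),
    )


def complete_genome(
    contig: NucleotideSequence,
    reads: list[NucleotideSequence],
    max_rounds: int = 20,
    min_anchor: int = 30,
    max_mismatch_rate: float = 0.05,
    min_support: int = 3,
    majority: float = 0.8,
    seed_k: int = 15,
) -> CompletionResult:
    """Alternate mapping and two-sided extension until both ends are stable.

    Extension never edits pre-existing contig bases, so the procedure
    cannot oscillate.  The final re-map recomputes depth and the mismatch
    profile; the result is COMPLETE when every consensus base is covered by
    at least ``min_support`` reads, else PARTIAL (also when the round limit
    is hit while still extending).
    """
    current = contig
    rounds: list[CompletionRound] = []
    hit_limit = False
    for rnd in range(1, max_rounds + 1):
        pile = map_reads(current, reads, min_anchor, max_mismatch_rate, seed_k)
        left_seq, lext = extend_terminus(pile, "left", min_support, majority)
        right_seq, rext = extend_terminus(pile, "right", min_support, majority)
        new = (
            left_seq.residues[: lext or 0]
            + current.residues
            + (right_seq.residues[len(right_seq.residues) - rext :] if rext else "")
        )
        current = NucleotideSequence(
            id=contig.id, residues=new, description=contig.description
        )
        rounds.append(
            CompletionRound(rnd, lext, rext, len(pile.alignments), len(new))
        )
        if lext == 0 and rext == 0:
            break
    else:
        hit_limit = True
    final = map_reads(current, reads, min_anchor, max_mismatch_rate, seed_k)
    complete = bool(np.all(final.depth >= min_support)) and not hit_limit
    return CompletionResult(
        genome=current,
        rounds=rounds,
        status="COMPLETE" if complete else "PARTIAL",
        pile=final,
    )


@dataclass
class CoverageReport:
    min_depth: int
    median_depth: float
    max_depth: int
    itr_median: float | None = None
    core_median: float | None = None


def coverage_report(
    pile: ReadPile, itr_length: int | None = None
) -> CoverageReport:
    """Depth summary, optionally split into ITR vs core regions."""
    d = pile.depth
    if d.size == 0 or not pile.alignments:
        return CoverageReport(0, 0.0, 0, None, None)
    rep = CoverageReport(
        min_depth=int(d.min()),
        median_depth=float(np.median(d)),
        max_depth=int(d.max()),
    )
    if itr_length and 2 * itr_length < d.size:
        itr = np.concatenate([d[:itr_length], d[-itr_length:]])
        rep.itr_median = float(np.median(itr))
        rep.core_median = float(np.median(d[itr_length:-itr_length]))
    return rep
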