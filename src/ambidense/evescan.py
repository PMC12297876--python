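"""Endogenous viral element detection in host assemblies.

Past germline integrations leave degraded fragments of a viral genome in
the host: single integrants, head-to-tail tandem arrays, and — after
neofunctionalization — loci whose viral reading frame splices onto a host
exon.  This module finds such integrants by seeded local alignment of the
viral genome against host scaffolds, chains collinear hits into tandem
arrays, and reconstructs GT..AG splice junctions that fuse a viral ORF to
downstream host coding sequence.

Alignment scoring is megablast-like (match +2, mismatch -3, affine gaps:
a gap of length g costs 5 + 2g).  Percent identity is computed over all
alignment columns, gaps included in the denominator.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass

from .core import Feature, NucleotideSequence, ProteinSequence, STOP_CODONS, CODON_TABLE, rc

GAP_FIRST = -7  # first gap base: open (-5) plus extend (-2)
GAP_EXT = -2
MATCH = 2
MISMATCH = -3


@dataclass
class AlignmentHit:
    query_start: int  # 1-based, forward strand of the query
    query_end: int
    subject_start: int
    subject_end: int
    strand: str
    score: int
    matches: int
    mismatches: int
    gaps: int
    columns: int

    @property
    def identity(self) -> float:
        return self.matches / self.columns if self.columns else 0.0

    @property
    def gap_fraction(self) -> float:
        return self.gaps / self.columns if self.columns else 0.0


@dataclass
class EveHit:
    scaffold: str
    host_start: int
    host_end: int
    viral_start: int
    viral_end: int
    strand: str
    identity: float
    gap_fraction: float
    length: int
    score: int
    label: str = ""


@dataclass
class TandemArray:
    members: list[EveHit]
    copy_number: int
    unit_length: int
    mean_inter_copy_identity: float


@dataclass
class FusionCandidate:
    donor: int  # scaffold coordinate of the G of the GT donor
    acceptor: int  # scaffold coordinate of the G of the AG acceptor
    intron_length: int
    start_codon: int
    protein: ProteinSequence
    viral_segment_nt: int  # exon-1 (integrant-derived) coding length
    host_segment_nt: int  # exon-2 coding length including the stop

    @property
    def aa_length(self) -> int:
        return len(self.protein.residues)


# ---------------------------------------------------------------------------
# Affine-gap Smith-Waterman (banded)


def _sw_region(
    q: str, s: str, diag_lo: int, diag_hi: int
) -> tuple[int, tuple[int, int, int, int], tuple[int, int, int]] | None:
    """Best local alignment restricted to diagonals j-i in [diag_lo, diag_hi].

    Returns (score, (q_start, q_end, s_start, s_end) 0-based inclusive,
    (matches, mismatches, gaps)) or None when nothing scores above zero.
    """
    m, n = len(q), len(s)
    diag_lo = max(diag_lo, -m + 1)
    diag_hi = min(diag_hi, n - 1)
    if diag_lo > diag_hi:
        return None
    width = diag_hi - diag_lo + 1
    NEG = -(10**9)
    # band-indexed rows: column b corresponds to j = i + diag_lo + b
    H_prev = [0] * (width + 2)
    E_prev = [NEG] * (width + 2)
    F_prev = [NEG] * (width + 2)
    ptr_H: list[list[int]] = []  # 0 stop, 1 diag, 2 gap-in-q (E), 3 gap-in-s (F)
    ptr_E: list[list[int]] = []  # 1 open, 0 extend
    ptr_F: list[list[int]] = []
    best = (0, -1, -1)
    H_rows = [H_prev]
    for i in range(1, m + 1):
        H_cur = [0] * (width + 2)
        E_cur = [NEG] * (width + 2)
        F_cur = [NEG] * (width + 2)
        pH = [0] * (width + 2)
        pE = [0] * (width + 2)
        pF = [0] * (width + 2)
        qc = q[i - 1]
        base_j = i + diag_lo - 1  # j at band column b=0 is base_j + b + ...
        for b in range(1, width + 1):
            j = i + diag_lo + b - 1
            if j < 1 or j > n:
                continue
            # E: gap in q -> j-1, same i -> band column b-1 of current row
            e_open = H_cur[b - 1] + GAP_FIRST
            e_ext = E_cur[b - 1] + GAP_EXT
            if e_open >= e_ext:
                E_cur[b], pE[b] = e_open, 1
            else:
                E_cur[b], pE[b] = e_ext, 0
            # F: gap in s -> i-1, same j -> band column b+1 of previous row
            f_open = H_prev[b + 1] + GAP_FIRST
            f_ext = F_prev[b + 1] + GAP_EXT
            if f_open >= f_ext:
                F_cur[b], pF[b] = f_open, 1
            else:
                F_cur[b], pF[b] = f_ext, 0
            diag = H_prev[b] + (MATCH if qc == s[j - 1] else MISMATCH)
            h, p = 0, 0
            if diag > h:
                h, p = diag, 1
            if E_cur[b] > h:
                h, p = E_cur[b], 2
            if F_cur[b] > h:
                h, p = F_cur[b], 3
            H_cur[b], pH[b] = h, p
            if h > best[0]:
                best = (h, i, b)
        ptr_H.append(pH)
        ptr_E.append(pE)
        ptr_F.append(pF)
        H_rows.append(H_cur)
        H_prev, E_prev, F_prev = H_cur, E_cur, F_cur
    if best[0] <= 0:
        return None
    score, i, b = best
    qe, se = i, i + diag_lo + b - 1
    matches = mismatches = gaps = 0
    state = "H"
    while i > 0:
        if state == "H":
            p = ptr_H[i - 1][b]
            if p == 0:
                break
            if p == 1:
                j = i + diag_lo + b - 1
                if q[i - 1] == s[j - 1]:
                    matches += 1
                else:
                    mismatches += 1
                i -= 1  # b unchanged: same diagonal
            elif p == 2:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            gaps += 1
            opened = ptr_E[i - 1][b] == 1
            b -= 1
            if opened:
                state = "H"
        else:  # F
            gaps += 1
            opened = ptr_F[i - 1][b] == 1
            i -= 1
            b += 1
            if opened:
                state = "H"
    qs, ss = i + 1, i + diag_lo + b
    return score, (qs, qe, ss, se), (matches, mismatches, gaps)


def _seed_clusters(q: str, s: str, k: int, band: int):
    """Cluster exact k-mer seed matches by diagonal; yields
    (q_lo, q_hi, s_lo, s_hi, diag_lo, diag_hi) windows (0-based, exclusive hi)."""
    index: dict[str, list[int]] = {}
    for i in range(len(q) - k + 1):
        index.setdefault(q[i : i + k], []).append(i)
    seeds = []  # (diag, qpos, spos)
    for j in range(len(s) - k + 1):
        for i in index.get(s[j : j + k], ()):
            seeds.append((j - i, i, j))
    if not seeds:
        return
    seeds.sort()
    cluster = [seeds[0]]
    for seed in seeds[1:]:
        if seed[0] - cluster[-1][0] <= band:
            cluster.append(seed)
        else:
            yield _cluster_window(cluster, q, s, k, band)
            cluster = [seed]
    yield _cluster_window(cluster, q, s, k, band)


def _cluster_window(cluster, q, s, k, band):
    diags = [c[0] for c in cluster]
    qpos = [c[1] for c in cluster]
    pad = 220
    q_lo = max(0, min(qpos) - pad)
    q_hi = min(len(q), max(qpos) + k + pad)
    d_lo, d_hi = min(diags) - band, max(diags) + band
    s_lo = max(0, q_lo + d_lo)
    s_hi = min(len(s), q_hi + d_hi)
    return q_lo, q_hi, s_lo, s_hi, d_lo, d_hi


def local_align(
    query: NucleotideSequence,
    subject: NucleotideSequence,
    min_score: int = 50,
    seed_k: int = 11,
    band: int = 24,
) -> list[AlignmentHit]:
    """Seeded Smith-Waterman with affine gaps, both strands of the query.

    For small problems (area up to 250k cells) the full dynamic program is
    run; larger ones are restricted to diagonal bands around exact 11-mer
    seed clusters.  Non-overlapping best hits (greedy by score on the
    subject axis) with score >= ``min_score`` are returned.
    """
    if not query.residues or not subject.residues:
        raise ValueError("local_align requires non-empty sequences")
    s = subject.residues
    Lq = len(query.residues)
    raw: list[AlignmentHit] = []
    for strand in "+-":
        qs = query.residues if strand == "+" else rc(query.residues)
        if len(qs) * len(s) <= 250_000:
            windows = [(0, len(qs), 0, len(s), -len(qs), len(s))]
        else:
            windows = list(_seed_clusters(qs, s, seed_k, band))
        for q_lo, q_hi, s_lo, s_hi, d_lo, d_hi in windows:
            sub_q = qs[q_lo:q_hi]
            sub_s = s[s_lo:s_hi]
            # diagonals in window coordinates
            w_lo = d_lo - (s_lo - q_lo)
            w_hi = d_hi - (s_lo - q_lo)
            res = _sw_region(sub_q, sub_s, w_lo, w_hi)
            if res is None:
                continue
            score, (qa, qb, sa, sb), (mat, mis, gap) = res
            if score < min_score:
                continue
            qa, qb = qa + q_lo, qb + q_lo  # 1-based on the oriented query
            sa, sb = sa + s_lo, sb + s_lo
            if strand == "+":
                q_start, q_end = qa, qb
            else:
                q_start, q_end = Lq - qb + 1, Lq - qa + 1
            raw.append(
                AlignmentHit(
                    query_start=q_start,
                    query_end=q_end,
                    subject_start=sa,
                    subject_end=sb,
                    strand=strand,
                    score=score,
                    matches=mat,
                    mismatches=mis,
                    gaps=gap,
                    columns=mat + mis + gap,
                )
            )
    raw.sort(key=lambda h: (-h.score, h.subject_start))
    kept: list[AlignmentHit] = []
    for h in raw:
        span = h.subject_end - h.subject_start + 1
        overlap = 0
        for k2 in kept:
            lo = max(h.subject_start, k2.subject_start)
            hi = min(h.subject_end, k2.subject_end)
            overlap = max(overlap, hi - lo + 1)
        if overlap <= 0.3 * span:
            kept.append(h)
    kept.sort(key=lambda h: h.subject_start)
    return kept


# ---------------------------------------------------------------------------
# EVE scanning


def scan_host_for_eves(
    viral: NucleotideSequence,
    scaffolds: list[NucleotideSequence],
    min_identity: float = 0.65,
    min_length: int = 200,
    annotation: list[Feature] | None = None,
    min_score: int = 50,
) -> list[EveHit]:
    """Local-align the viral genome against each scaffold and report
    integrant candidates above the identity/length thresholds, labelled by
    the viral annotation they overlap when one is supplied."""
    out: list[EveHit] = []
    for scaffold in scaffolds:
        for h in local_align(viral, scaffold, min_score=min_score):
            if h.columns < min_length or h.identity < min_identity:
                continue
            label = ""
            if annotation is not None:
                names = [
                    f.attributes.get("name", f.kind.value)
                    for f in annotation
                    if f.kind.value in ("ORF", "ITR5", "ITR3")
                    and f.overlaps(h.query_start, h.query_end)
                ]
                label = ",".join(dict.fromkeys(names))
            out.append(
                EveHit(
                    scaffold=scaffold.id,
                    host_start=h.subject_start,
                    host_end=h.subject_end,
                    viral_start=h.query_start,
                    viral_end=h.query_end,
                    strand=h.strand,
                    identity=h.identity,
                    gap_fraction=h.gap_fraction,
                    length=h.columns,
                    score=h.score,
                    label=label,
                )
            )
    out.sort(key=lambda e: (e.scaffold, e.host_start))
    return out


def detect_tandem_array(hits: list[EveHit]) -> list[TandemArray]:
    """Chain collinear same-strand hits into head-to-tail tandem arrays.

    Consecutive copies must be on one scaffold and strand with the gap
    between aligned segments under 20% of the array period (the
    start-to-start spacing — local alignments trim divergent copy tails,
    so the aligned-segment gap overstates the true inter-copy gap);
    singletons are arrays of copy number 1.  The unit length reported is
    the period for arrays, the aligned length for singletons.  Inter-copy
    identity is measured between adjacent member segments (ungapped column
    identity over the shorter unit).
    """
    arrays: list[TandemArray] = []
    by_scaffold: dict[str, list[EveHit]] = {}
    for h in hits:
        by_scaffold.setdefault(h.scaffold, []).append(h)
    for scaffold_hits in by_scaffold.values():
        scaffold_hits.sort(key=lambda h: h.host_start)
        chain: list[EveHit] = []
        for h in scaffold_hits:
            if not chain:
                chain = [h]
                continue
            prev = chain[-1]
            spacing = h.host_start - prev.host_start
            gap = h.host_start - prev.host_end - 1
            same = (
                h.strand == prev.strand
                and abs((h.host_end - h.host_start) - (prev.host_end - prev.host_start))
                <= 0.2 * spacing
                and gap < 0.2 * spacing
            )
            if same:
                chain.append(h)
            else:
                arrays.append(_finish_array(chain))
                chain = [h]
        if chain:
            arrays.append(_finish_array(chain))
    return arrays


def _finish_array(chain: list[EveHit]) -> TandemArray:
    if len(chain) > 1:
        spacings = sorted(
            b.host_start - a.host_start for a, b in zip(chain, chain[1:])
        )
        unit = spacings[len(spacings) // 2]  # the array period
    else:
        unit = chain[0].host_end - chain[0].host_start + 1
    ident = 1.0
    if len(chain) > 1:
        idents = [
            _ungapped_identity(a, b) for a, b in zip(chain, chain[1:])
        ]
        ident = sum(idents) / len(idents)
    return TandemArray(
        members=chain,
        copy_number=len(chain),
        unit_length=unit,
        mean_inter_copy_identity=ident,
    )


def _ungapped_identity(a: EveHit, b: EveHit) -> float:
    sa = getattr(a, "_segment", None)
    sb = getattr(b, "_segment", None)
    if sa is None or sb is None:
        return (a.identity + b.identity) / 2  # fall back to viral identities
    n = min(len(sa), len(sb))
    return sum(x == y for x, y in zip(sa[:n], sb[:n])) / n if n else 1.0


def attach_segments(hits: list[EveHit], scaffolds: list[NucleotideSequence]) -> None:
    """Attach host-segment strings to hits so arrays can report true
    inter-copy identity (optional; detect_tandem_array works without it)."""
    by_id = {s.id: s for s in scaffolds}
    for h in hits:
        scaf = by_id.get(h.scaffold)
        if scaf is not None:
            h._segment = scaf.slice(h.host_start, h.host_end)  # type: ignore[attr-defined]


# ---------------------------------------------------------------------------
# Splice-fusion reconstruction


def find_splice_fusion(
    scaffold: NucleotideSequence,
    eve: EveHit,
    min_intron: int = 60,
    max_intron: int = 5000,
    min_fusion_aa: int = 100,
) -> list[FusionCandidate]:
    """Reconstruct GT..AG splice events fusing a viral ORF to host sequence.

    Donors (GT) are enumerated inside the EVE, acceptors (AG) downstream in
    the host within the intron-length bounds; each spliced transcript is
    scanned for an ORF that starts at an AUG inside the EVE and crosses the
    junction.  Candidates are ranked by spliced-ORF length.
    """
    if eve.strand != "-" and eve.strand != "+":
        raise ValueError("EVE strand must be + or -")
    if eve.strand == "-":
        raise ValueError(
            "minus-strand EVE: reverse-complement the scaffold and re-scan"
        )
    s = scaffold.residues
    lo, hi = eve.host_start, eve.host_end
    # a local alignment trims low-identity tails, so the integrant (and its
    # donor) can extend somewhat past the reported hit end
    hi_pad = min(len(s) - 1, hi + 150)
    donors = [p for p in range(lo, hi_pad + 1) if s[p - 1 : p + 1] == "GT"]
    acceptor_ends = [p for p in range(lo, len(s) + 1) if s[p - 2 : p] == "AG"]
    starts = [p for p in range(lo, hi - 2) if s[p - 1 : p + 2] == "ATG"]
    # stop-free extent of each start within its frame (pre-splice)
    candidates: list[FusionCandidate] = []
    exon2_cache: dict[tuple[int, int], tuple[int, bool]] = {}

    def exon2_aa(acc: int, phase: int) -> tuple[int, bool]:
        """Codons contributed past the acceptor when ``phase`` exon-1 bases
        dangle; returns (aa_count, stop_found)."""
        key = (acc, phase)
        if key in exon2_cache:
            return exon2_cache[key]
        pos = acc + (3 - phase) % 3  # 0-based index of the first full codon
        count = 1 if phase else 0  # the junction codon
        aa = 0
        stop = False
        i = pos
        while i + 3 <= len(s):
            codon = s[i : i + 3]
            if codon in STOP_CODONS:
                stop = True
                break
            aa += 1
            i += 3
        exon2_cache[key] = (aa + count, stop)
        return exon2_cache[key]

    for m in starts:
        # how far can exon 1 run before an in-frame stop?
        ext = hi
        i = m - 1
        while i + 3 <= len(s):
            if s[i : i + 3] in STOP_CODONS:
                ext = i  # 0-based position of the stop: donor must be <= ext
                break
            i += 3
        else:
            ext = len(s)
        for d in donors:
            if d <= m + 2 or d - 1 >= ext + 4:  # full stop codon inside exon 1
                continue
            exon1 = d - m  # nt of exon 1 (positions m .. d-1)
            phase = exon1 % 3
            a_lo = bisect_left(acceptor_ends, d + min_intron - 1)
            a_hi = bisect_right(acceptor_ends, d + max_intron - 1)
            for acc in acceptor_ends[a_lo:a_hi]:
                aa2, stop = exon2_aa(acc, phase)
                if not stop:
                    continue  # ORF must terminate within the scaffold
                total = exon1 // 3 + aa2
                if total < min_fusion_aa:
                    continue
                if aa2 == 0:
                    continue  # must cross the junction
                spliced = s[m - 1 : d - 1] + s[acc:]
                protein = _translate_str(spliced)
                if len(protein) != total:
                    continue  # junction codon happened to be a stop
                candidates.append(
                    FusionCandidate(
                        donor=d,
                        acceptor=acc,
                        intron_length=acc - d + 1,
                        start_codon=m,
                        protein=ProteinSequence(
                            id=f"{scaffold.id}:{m}:fusion", residues=protein
                        ),
                        viral_segment_nt=exon1,
                        host_segment_nt=3 * total + 3 - exon1,
                    )
                )
    candidates.sort(key=lambda c: (-c.aa_length, c.intron_length))
    return candidates[:50]


def _translate_str(s: str) -> str:
    aas = []
    for i in range(0, len(s) - 2, 3):
        codon = s[i : i + 3]
        if codon in STOP_CODONS:
            break
        aas.append(CODON_TABLE.get(codon, "X"))
    return "".join(aas)
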