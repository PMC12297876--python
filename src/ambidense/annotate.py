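"""Ambisense transcription-map annotation.

Produces the transcription map of an ambisense densovirus genome: the
rightward NS unit (NS1/Rep with an internal, leaky-scanned NS2 ORF) and the
converging leftward VP unit (capsid protein, plus an internal promoter that
would express an N-terminally truncated VP), together with the cis-elements
that delimit them (TATA / TATA-like promoter elements, predicted TSS,
polyadenylation signals) and conserved protein motifs of the Rep
endonuclease (HuH, YuxK).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

from .core import (
    Feature,
    FeatureKind,
    NucleotideSequence,
    ProteinSequence,
    STOP_CODONS,
    rc,
    translate,
)

logger = logging.getLogger("ambidense")

TATA_MOTIF = "TATAAA"
TATA_LIKE_MOTIF = "TAAATAAA"
POLYA_MOTIF = "AATAAA"
#: TSS predicted this many nt downstream of the promoter element start
#: (consistent with the observed TATA-like -> TSS spacing in ambidensoviruses)
TSS_OFFSET = 32

HYDROPHOBIC = set("AVLIMFWC")


@dataclass
class Orf:
    """An AUG-to-stop open reading frame with its translation product."""

    feature: Feature  # interval includes the stop codon, forward coordinates
    protein: ProteinSequence

    @property
    def aa_length(self) -> int:
        return len(self.protein.residues)

    @property
    def strand(self) -> str:
        return self.feature.strand

    @property
    def start_codon_interval(self) -> tuple[int, int]:
        f = self.feature
        if f.strand == "+":
            return (f.start, f.start + 2)
        return (f.end - 2, f.end)


@dataclass
class TranscriptionUnit:
    direction: str  # "rightward_NS" or "leftward_VP"
    promoter: Feature | None
    outer_promoter: Feature | None
    tss: Feature | None
    orfs: list[Orf]
    polya: Feature | None
    converging: bool = False
    leader_uaug_count: int | None = None
    warnings: list[str] = field(default_factory=list)


@dataclass
class LeakyScanReport:
    leader_uaug_count: int
    intervening_aug_count: int

    @property
    def verdict(self) -> str:
        return (
            "leaky_scanning_plausible"
            if self.intervening_aug_count == 0
            else "blocked"
        )


@dataclass
class TruncatedVpPrediction:
    internal_promoter: Feature
    tss: Feature
    start_interval: tuple[int, int]
    protein: ProteinSequence
    in_frame_with_vp: bool
    warnings: list[str] = field(default_factory=list)

    @property
    def aa_length(self) -> int:
        return len(self.protein.residues)


@dataclass
class TranscriptionMap:
    ns_unit: TranscriptionUnit
    vp_unit: TranscriptionUnit
    leaky_scan: LeakyScanReport
    truncated_vp: TruncatedVpPrediction | None


# ---------------------------------------------------------------------------
# ORF finding


def find_orfs(genome: NucleotideSequence, min_aa: int = 100) -> list[Orf]:
    """AUG-to-stop ORFs on all six frames, at least ``min_aa`` codons.

    Per stop codon the first AUG after the previous in-frame stop opens the
    ORF (the NCBI ORF-finder convention), so nested same-frame starts are
    subsumed while nested ORFs in different frames are retained.  Reverse
    ORFs are reported by their forward-strand interval.
    """
    L = len(genome.residues)
    orfs: list[Orf] = []
    for strand in "+-":
        s = genome.residues if strand == "+" else rc(genome.residues)
        for frame in range(3):
            start: int | None = None
            for i in range(frame, len(s) - 2, 3):
                codon = s[i : i + 3]
                if codon in STOP_CODONS:
                    if start is not None:
                        aa = (i - start) // 3
                        if aa >= min_aa:
                            orfs.append(
                                _make_orf(genome, s, strand, start, i + 2, L)
                            )
                    start = None
                elif codon == "ATG" and start is None:
                    start = i
    orfs.sort(key=lambda o: (o.feature.start, o.feature.strand))
    return orfs


def _make_orf(
    genome: NucleotideSequence, s: str, strand: str, a: int, b: int, L: int
) -> Orf:
    # a..b are 0-based inclusive on the reading strand, stop codon included
    if strand == "+":
        start, end = a + 1, b + 1
        frame_start = start
    else:
        start, end = L - b, L - a
        frame_start = end
    protein = translate(genome, frame_start, strand)
    feature = Feature(
        kind=FeatureKind.ORF,
        start=start,
        end=end,
        strand=strand,
        attributes={"aa_length": str(len(protein.residues))},
    )
    protein.source_orf = feature
    return Orf(feature=feature, protein=protein)


# ---------------------------------------------------------------------------
# cis-elements


def scan_cis_elements(genome: NucleotideSequence) -> list[Feature]:
    """Exact-match scan for TATAAA / TAAATAAA / AATAAA on both strands.

    Every occurrence is reported in forward coordinates; assigning roles
    (promoter vs terminator) is the job of :func:`build_transcription_map`.
    """
    motifs = [
        (TATA_MOTIF, FeatureKind.TATA),
        (TATA_LIKE_MOTIF, FeatureKind.TATA_LIKE),
        (POLYA_MOTIF, FeatureKind.POLYA),
    ]
    L = len(genome.residues)
    feats: list[Feature] = []
    for motif, kind in motifs:
        for strand in "+-":
            pattern = motif if strand == "+" else rc(motif)
            for m in re.finditer(f"(?={pattern})", genome.residues):
                start = m.start() + 1
                feats.append(
                    Feature(
                        kind=kind,
                        start=start,
                        end=start + len(motif) - 1,
                        strand=strand,
                    )
                )
    feats.sort(key=lambda f: (f.start, f.kind.value, f.strand))
    return feats


def _count_aug(s: str, lo: int, hi: int) -> int:
    """Forward-strand AUG occurrences with start position in [lo, hi] (1-based)."""
    if hi < lo:
        return 0
    region = s[lo - 1 : hi + 2]  # allow codon to extend past hi
    return sum(
        1 for m in re.finditer("(?=ATG)", region) if m.start() + lo <= hi
    )


def _rev_aug_positions(s: str, lo: int, hi: int) -> list[int]:
    """5'-base forward coordinates of minus-strand AUGs within [lo, hi].

    A minus-strand AUG whose 5' base sits at forward coordinate q reads
    across forward positions q-2..q, which carry CAT on the forward strand.
    """
    out = []
    for m in re.finditer("(?=CAT)", s):
        q = m.start() + 3  # forward coord of the reverse-sense A
        if lo <= q <= hi:
            out.append(q)
    return sorted(out, reverse=True)


# ---------------------------------------------------------------------------
# Transcription map


def build_transcription_map(
    genome: NucleotideSequence,
    orfs: list[Orf] | None = None,
    cis_elements: list[Feature] | None = None,
    min_aa: int = 100,
) -> TranscriptionMap:
    if orfs is None:
        orfs = find_orfs(genome, min_aa=min_aa)
    if cis_elements is None:
        cis_elements = scan_cis_elements(genome)
    fwd = [o for o in orfs if o.strand == "+"]
    rev = [o for o in orfs if o.strand == "-"]
    if not fwd or not rev:
        raise ValueError("transcription map needs at least one ORF per strand")
    s = genome.residues
    L = len(s)

    def by_kind(kind: FeatureKind, strand: str) -> list[Feature]:
        return [f for f in cis_elements if f.kind is kind and f.strand == strand]

    # --- NS (rightward) unit -------------------------------------------------
    ns1 = max(fwd, key=lambda o: o.aa_length)
    ns_warn: list[str] = []
    nested = [
        o
        for o in fwd
        if o is not ns1
        and o.feature.start > ns1.feature.start
        and o.feature.end <= ns1.feature.end + 3
        and (o.feature.start - ns1.feature.start) % 3 != 0
    ]
    ns2 = max(nested, key=lambda o: o.aa_length) if nested else None

    tata_like_up = [
        f for f in by_kind(FeatureKind.TATA_LIKE, "+") if f.end < ns1.feature.start
    ]
    ns_promoter = max(tata_like_up, key=lambda f: f.start) if tata_like_up else None
    itr_tatas = [
        f
        for f in by_kind(FeatureKind.TATA, "+")
        if ns_promoter is None or f.end < ns_promoter.start
    ]
    ns_outer = max(itr_tatas, key=lambda f: f.start) if itr_tatas else None
    ns_tss = None
    if ns_promoter is not None:
        t = ns_promoter.start + TSS_OFFSET
        ns_tss = Feature(kind=FeatureKind.TSS, start=t, end=min(t + 2, L), strand="+")
    else:
        ns_warn.append("no TATA-like promoter element upstream of NS1")
    polya_after = [
        f for f in by_kind(FeatureKind.POLYA, "+") if f.start > ns1.feature.end
    ]
    ns_polya = min(polya_after, key=lambda f: f.start) if polya_after else None

    # --- leaky scanning report ----------------------------------------------
    scan_from = None
    if ns_outer is not None:
        scan_from = ns_outer.start + TSS_OFFSET
    elif ns_tss is not None:
        scan_from = ns_tss.start
    leader_count = (
        _count_aug(s, scan_from, ns1.feature.start - 1) if scan_from else 0
    )
    if ns2 is not None:
        intervening = _count_aug(
            s, ns1.feature.start + 1, ns2.feature.start - 1
        )
    else:
        intervening = 0
    leaky = LeakyScanReport(leader_count, intervening)

    # --- VP (leftward) unit --------------------------------------------------
    vp = max(rev, key=lambda o: o.aa_length)
    vp_warn: list[str] = []
    vp_aug_end = vp.feature.end
    tata_down = [
        f for f in by_kind(FeatureKind.TATA, "-") if f.start > vp_aug_end
    ]
    vp_promoter = min(tata_down, key=lambda f: f.start) if tata_down else None
    vp_tss = None
    if vp_promoter is not None:
        t = vp_promoter.end - TSS_OFFSET  # reverse-sense: downstream = leftward
        vp_tss = Feature(kind=FeatureKind.TSS, start=max(t - 2, 1), end=t, strand="-")
    else:
        vp_warn.append("no TATA element in the 3' ITR upstream of VP")
    vp_polya_cands = [
        f for f in by_kind(FeatureKind.POLYA, "-") if f.end < vp.feature.start
    ]
    vp_polya = max(vp_polya_cands, key=lambda f: f.end) if vp_polya_cands else None
    vp_leader = (
        len(_rev_aug_positions(s, vp_aug_end + 1, vp_tss.end - 1))
        if vp_tss is not None
        else None
    )

    # --- truncated VP from the internal promoter ------------------------------
    truncated: TruncatedVpPrediction | None = None
    internal = [
        f
        for f in by_kind(FeatureKind.TATA_LIKE, "-")
        if vp.feature.start < f.start and f.end < vp.feature.end
    ]
    for elem in sorted(internal, key=lambda f: -f.end):
        t = elem.end - TSS_OFFSET
        tss = Feature(kind=FeatureKind.TSS, start=max(t - 2, 1), end=t, strand="-")
        augs = _rev_aug_positions(s, vp.feature.start + 3, t)
        if not augs:
            continue
        q = augs[0]  # first AUG downstream (leftward) of the internal TSS
        protein = translate(genome, q, "-")
        in_frame = (vp_aug_end - q) % 3 == 0
        warnings = []
        if not in_frame:
            warnings.append(
                "first downstream AUG is out of frame with VP; truncated VP demoted"
            )
            logger.warning(warnings[-1])
        truncated = TruncatedVpPrediction(
            internal_promoter=elem,
            tss=tss,
            start_interval=(q - 2, q),
            protein=protein,
            in_frame_with_vp=in_frame,
            warnings=warnings,
        )
        break

    ns_polya_pos = ns_polya.start if ns_polya else ns1.feature.end
    converging = ns_polya_pos < vp.feature.end
    ns_unit = TranscriptionUnit(
        direction="rightward_NS",
        promoter=ns_promoter,
        outer_promoter=ns_outer,
        tss=ns_tss,
        orfs=[o for o in (ns1, ns2) if o is not None],
        polya=ns_polya,
        converging=converging,
        leader_uaug_count=leader_count if scan_from else None,
        warnings=ns_warn,
    )
    vp_unit = TranscriptionUnit(
        direction="leftward_VP",
        promoter=vp_promoter,
        outer_promoter=None,
        tss=vp_tss,
        orfs=[vp],
        polya=vp_polya,
        converging=converging,
        leader_uaug_count=vp_leader,
        warnings=vp_warn,
    )
    return TranscriptionMap(ns_unit, vp_unit, leaky, truncated)


# ---------------------------------------------------------------------------
# Protein motifs


DEFAULT_MOTIFS: dict[str, str] = {
    # HuH endonuclease/nickase motifs of parvoviral NS1/Rep:
    # "u" = hydrophobic, "x" = any residue
    "HuH": "HuH",
    "YuxK": "YuxK",
}


def _motif_matches(protein: str, pattern: str) -> list[int]:
    """1-based start positions where the pattern matches (u=hydrophobic, x=any)."""
    out = []
    k = len(pattern)
    for i in range(len(protein) - k + 1):
        ok = True
        for j, p in enumerate(pattern):
            aa = protein[i + j]
            if p == "x":
                continue
            if p == "u":
                if aa not in HYDROPHOBIC:
                    ok = False
                    break
            elif aa != p:
                ok = False
                break
        if ok:
            out.append(i + 1)
    return out


def nickase_motif_pair(protein: ProteinSequence) -> tuple[int, int] | None:
    """The (HuH, YuxK) motif pair of a Rep endonuclease/nickase domain.

    In parvoviral NS1/Rep proteins the two motifs co-occur with the YuxK
    roughly 40-70 residues downstream of the HuH; isolated chance matches
    of either pattern are common, co-occurring pairs are not.  Returns the
    first such pair (1-based aa starts), or None.
    """
    feats = scan_protein_motifs(protein)
    huh = sorted(f.start for f in feats if f.attributes["name"] == "HuH")
    yuxk = sorted(f.start for f in feats if f.attributes["name"] == "YuxK")
    for h in huh:
        for y in yuxk:
            if 40 <= y - h <= 70:
                return (h, y)
    return None


def scan_protein_motifs(
    protein: ProteinSequence,
    motifs: dict[str, str] | None = None,
) -> list[Feature]:
    """Scan a protein for HuH / YuxK-style motifs (1-based aa coordinates)."""
    if motifs is None:
        motifs = DEFAULT_MOTIFS
    feats: list[Feature] = []
    for name, pattern in motifs.items():
        for start in _motif_matches(protein.residues, pattern):
            end = start + len(pattern) - 1
            feats.append(
                Feature(
                    kind=FeatureKind.PROTEIN_MOTIF,
                    start=start,
                    end=end,
                    strand="+",
                    attributes={
                        "name": name,
                        "match": protein.residues[start - 1 : end],
                    },
                )
            )
    feats.sort(key=lambda f: (f.start, f.attributes.get("name", "")))
    return feats
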