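"""In silico PCR: diagnostic amplicon prediction and primer-presence screens.

Mirrors a wet-lab diagnostic assay: a primer pair amplifies a product only
where the forward primer matches the template plus strand and the reverse
primer matches the minus strand downstream of it (and symmetrically on the
other orientation).  The 3'-terminal base of each primer must match exactly
even when internal mismatches are tolerated, since polymerase extension
from a mismatched 3' end is inefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import NucleotideSequence, rc


@dataclass
class PrimerPair:
    forward: str
    reverse: str
    max_mismatch: int = 0

    def __post_init__(self) -> None:
        self.forward = self.forward.upper()
        self.reverse = self.reverse.upper()
        for name, p in (("forward", self.forward), ("reverse", self.reverse)):
            if not 15 <= len(p) <= 35:
                raise ValueError(f"{name} primer must be 15..35 nt, got {len(p)}")


@dataclass
class Amplicon:
    template_id: str
    start: int  # 5' end of the leftmost primer site (forward coordinates)
    end: int    # 5' end of the rightmost (reverse-binding) primer site
    length: int
    orientation: str  # "forward" if the forward primer is on the plus strand

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


def _plus_sites(template: str, primer: str, max_mm: int) -> list[int]:
    """1-based start positions where the primer matches the plus strand,
    3'-terminal base exactly."""
    k = len(primer)
    out = []
    for i in range(len(template) - k + 1):
        if template[i + k - 1] != primer[-1]:
            continue
        mm = sum(a != b for a, b in zip(template[i : i + k], primer))
        if mm <= max_mm:
            out.append(i + 1)
    return out


def _minus_sites(template: str, primer: str, max_mm: int) -> list[int]:
    """1-based positions of the primer's 5' end on the forward axis for
    minus-strand matches (the primer reads rightward on the minus strand,
    so its site spans [p - k + 1, p] on the forward axis)."""
    probe = rc(primer)  # forward-strand image; primer 3' end = probe[0]
    k = len(primer)
    out = []
    for i in range(len(template) - k + 1):
        if template[i] != probe[0]:
            continue
        mm = sum(a != b for a, b in zip(template[i : i + k], probe))
        if mm <= max_mm:
            out.append(i + k)  # forward coordinate of the primer 5' end
    return out


def in_silico_pcr(
    template: NucleotideSequence,
    pair: PrimerPair,
    max_len: int = 5000,
) -> list[Amplicon]:
    """All products of the primer pair on the template, both orientations.

    An empty list mirrors a PCR-negative lane.
    """
    s = template.residues
    mm = pair.max_mismatch
    amps: list[Amplicon] = []
    for left, right, orientation in (
        (pair.forward, pair.reverse, "forward"),
        (pair.reverse, pair.forward, "reverse"),
    ):
        for p in _plus_sites(s, left, mm):
            for q in _minus_sites(s, right, mm):
                length = q - p + 1
                if len(left) + len(right) <= length <= max_len:
                    amps.append(Amplicon(template.id, p, q, length, orientation))
    # identical products found from both primer assignments are one product
    seen = set()
    unique = []
    for a in sorted(amps, key=lambda a: (a.start, a.end)):
        key = (a.start, a.end)
        if key not in seen:
            seen.add(key)
            unique.append(a)
    return unique


@dataclass
class PrimerHitReport:
    genome_id: str
    forward_sites: int
    reverse_sites: int
    amplicons: int


def primer_uniqueness(
    pair: PrimerPair,
    genomes: list[NucleotideSequence],
    target_id: str | None = None,
    max_len: int = 5000,
) -> tuple[list[PrimerHitReport], bool]:
    """Per-genome primer site and amplicon counts, plus a specificity verdict.

    The assay is "specific" iff no genome other than the target yields any
    amplicon.  With no target given, every genome is treated as non-target
    (a pure exclusivity screen).
    """
    rows: list[PrimerHitReport] = []
    specific = True
    for g in genomes:
        s = g.residues
        mm = pair.max_mismatch
        fwd = len(_plus_sites(s, pair.forward, mm)) + len(
            _minus_sites(s, pair.forward, mm)
        )
        rev = len(_plus_sites(s, pair.reverse, mm)) + len(
            _minus_sites(s, pair.reverse, mm)
        )
        n_amp = len(in_silico_pcr(g, pair, max_len))
        rows.append(PrimerHitReport(g.id, fwd, rev, n_amp))
        if g.id != target_id and n_amp > 0:
            specific = False
    return rows, specific
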