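"""Host-read subtraction and redundant-read enrichment.

Before assembling a low-titre virus from total-DNA sequencing, host-derived
reads are subtracted and highly redundant (virus-enriched) reads are kept.
Host subtraction here is a canonical k-mer membership filter against the
host reference(s): a read is called host when more than ``max_host_fraction``
of its k-mers occur in the host index.  This has the same intent as mapping
reads to the host references and keeping the unmapped fraction, while being
self-contained and exactly reproducible.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

from .core import NucleotideSequence, rc

logger = logging.getLogger("ambidense")


@dataclass
class KmerIndex:
    k: int = 31
    kmers: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.k % 2 == 0 or not 11 <= self.k <= 63:
            raise ValueError("k must be odd and in 11..63")

    @classmethod
    def build(cls, references: list[NucleotideSequence], k: int = 31) -> "KmerIndex":
        idx = cls(k=k)
        for ref in references:
            idx.add(ref)
        return idx

    def add(self, ref: NucleotideSequence) -> None:
        s = ref.residues
        k = self.k
        for i in range(len(s) - k + 1):
            kmer = s[i : i + k]
            if "N" in kmer:
                continue
            self.kmers.add(min(kmer, rc(kmer)))

    def __contains__(self, kmer: str) -> bool:
        return min(kmer, rc(kmer)) in self.kmers

    def fraction_in(self, read: str) -> float:
        k = self.k
        n = len(read) - k + 1
        if n <= 0:
            return 0.0
        hits = sum(1 for i in range(n) if min(read[i : i + k], rc(read[i : i + k])) in self.kmers)
        return hits / n


def host_filter(
    reads: list[NucleotideSequence],
    index: KmerIndex,
    max_host_fraction: float = 0.5,
) -> tuple[list[NucleotideSequence], list[NucleotideSequence]]:
    """Partition reads into (kept, removed); removed = host-like.

    A read is removed iff the fraction of its k-mers found in the host
    index exceeds ``max_host_fraction``.  Reads shorter than k cannot be
    classified and are kept with a warning.  The partition is exhaustive
    and disjoint; paired mates are filtered independently.
    """
    kept: list[NucleotideSequence] = []
    removed: list[NucleotideSequence] = []
    for read in reads:
        if len(read.residues) < index.k:
            logger.warning(
                "read %s shorter than k=%d: kept unclassified", read.id, index.k
            )
            kept.append(read)
            continue
        if index.fraction_in(read.residues) > max_host_fraction:
            removed.append(read)
        else:
            kept.append(read)
    return kept, removed


def enrich_redundant(
    reads: list[NucleotideSequence],
    min_count: int = 10,
) -> list[tuple[str, int]]:
    """Collapse exact-duplicate read sequences and keep the redundant ones.

    Returns (unique sequence, count) pairs with count >= ``min_count``,
    sorted by descending count then lexicographically.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    counts = Counter(r.residues for r in reads)
    out = [(s, c) for s, c in counts.items() if c >= min_count]
    out.sort(key=lambda t: (-t[1], t[0]))
    return out
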