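"""Sequence and feature data model shared by every pipeline stage.

Coordinates are 1-based, fully inclusive, and always expressed on the
forward strand of the sequence they annotate, matching the convention of
GFF3 and of published densovirus genome maps (a reverse-strand start codon
is still reported by its forward-strand interval).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Data import CodonTable

logger = logging.getLogger("ambidense")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = re.compile(r"[^ACGTN]")

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
CODON_TABLE: dict[str, str] = dict(_STANDARD_TABLE.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_STANDARD_TABLE.stop_codons)
START_CODON = "ATG"


class Topology(str, Enum):
    LINEAR = "linear"
    CIRCULAR = "circular"


@dataclass
class NucleotideSequence:
    """An identified A/C/G/T/N string: genome, read, contig or host scaffold."""

    id: str
    residues: str
    topology: Topology = Topology.LINEAR
    quality: str | None = None  # FASTQ qualities, optional downstream
    description: str = ""

    def __post_init__(self) -> None:
        self.residues = self.residues.upper()
        if _VALID.search(self.residues):
            self.residues = _VALID.sub("N", self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def slice(self, start: int, end: int) -> str:
        """Subsequence by 1-based inclusive coordinates."""
        if not (1 <= start <= end <= len(self.residues)):
            raise IndexError(
                f"slice {start}..{end} out of bounds for {self.id!r} "
                f"(length {len(self.residues)})"
            )
        return self.residues[start - 1 : end]


class FeatureKind(str, Enum):
    ITR5 = "ITR5"
    ITR3 = "ITR3"
    HAIRPIN = "HAIRPIN"
    FLIPFLOP = "FLIPFLOP"
    G4 = "G4"
    ORF = "ORF"
    TATA = "TATA"
    TATA_LIKE = "TATA_LIKE"
    TSS = "TSS"
    POLYA = "POLYA"
    PRIMER_SITE = "PRIMER_SITE"
    EVE = "EVE"
    INTRON = "INTRON"
    PROTEIN_MOTIF = "PROTEIN_MOTIF"


#: SO-compatible GFF3 type strings for each feature kind.
_SO_TYPE = {
    FeatureKind.ITR5: "inverted_repeat",
    FeatureKind.ITR3: "inverted_repeat",
    FeatureKind.HAIRPIN: "hairpin_loop",
    FeatureKind.FLIPFLOP: "sequence_secondary_structure",
    FeatureKind.G4: "G_quartet",
    FeatureKind.ORF: "ORF",
    FeatureKind.TATA: "TATA_box",
    FeatureKind.TATA_LIKE: "promoter_element",
    FeatureKind.TSS: "TSS",
    FeatureKind.POLYA: "polyA_signal_sequence",
    FeatureKind.PRIMER_SITE: "primer_binding_site",
    FeatureKind.EVE: "transposable_element",  # nearest SO term for an integrant
    FeatureKind.INTRON: "intron",
    FeatureKind.PROTEIN_MOTIF: "polypeptide_motif",
}


@dataclass
class Feature:
    """A typed, stranded annotation in 1-based inclusive forward coordinates."""

    kind: FeatureKind
    start: int
    end: int
    strand: str = "+"
    score: float | None = None
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid interval {self.start}..{self.end}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, start: int, end: int) -> bool:
        return self.start <= end and start <= self.end


@dataclass
class ProteinSequence:
    """Translation product of an ORF; length excludes the stop codon."""

    id: str
    residues: str
    source_orf: Feature | None = None

    def __len__(self) -> int:
        return len(self.residues)


# ---------------------------------------------------------------------------
# Elementary operations


def reverse_complement(seq: NucleotideSequence | str) -> NucleotideSequence | str:
    """Watson-Crick reverse complement; N maps to N, length preserved."""
    if isinstance(seq, str):
        return seq.translate(_COMPLEMENT)[::-1]
    return NucleotideSequence(
        id=seq.id,
        residues=seq.residues.translate(_COMPLEMENT)[::-1],
        topology=seq.topology,
        description=seq.description,
    )


def rc(s: str) -> str:
    """Reverse complement of a plain string (internal shorthand)."""
    return s.translate(_COMPLEMENT)[::-1]


def translate(
    seq: NucleotideSequence, frame_start: int, strand: str = "+"
) -> ProteinSequence:
    """Translate from ``frame_start`` (1-based) in the given direction.

    Standard genetic code; stops at and excludes the first stop codon.
    Codons containing N translate to X.  On the minus strand, ``frame_start``
    is the forward coordinate of the first base read (the 5' base of the
    reverse-sense frame), so reading proceeds toward coordinate 1.
    """
    n = len(seq.residues)
    if not (1 <= frame_start <= n):
        raise IndexError(f"frame_start {frame_start} out of range 1..{n}")
    if strand == "+":
        coding = seq.residues[frame_start - 1 :]
    else:
        coding = rc(seq.residues[:frame_start])
    if len(coding) < 3:
        raise ValueError("fewer than one full codon from frame_start")
    aas: list[str] = []
    for i in range(0, len(coding) - 2, 3):
        codon = coding[i : i + 3]
        if codon in STOP_CODONS:
            break
        aas.append(CODON_TABLE.get(codon, "X"))
    return ProteinSequence(id=f"{seq.id}:{frame_start}{strand}", residues="".join(aas))


# ---------------------------------------------------------------------------
# File formats


def load_sequences(path: str | Path, format: str = "fasta") -> list[NucleotideSequence]:
    """Read FASTA/FASTQ records; residues uppercased, non-ACGTN mapped to N."""
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format {format!r}")
    path = Path(path)
    records = []
    try:
        for rec in SeqIO.parse(str(path), format):
            raw = str(rec.seq).upper()
            if _VALID.search(raw):
                logger.warning(
                    "record %s: non-ACGTN characters replaced with N", rec.id
                )
            qual = None
            if format == "fastq":
                quals = rec.letter_annotations.get("phred_quality")
                if quals is not None:
                    qual = "".join(chr(q + 33) for q in quals)
            records.append(
                NucleotideSequence(
                    id=rec.id,
                    residues=raw,
                    quality=qual,
                    description=rec.description,
                )
            )
    except ValueError as exc:  # Biopython names the offending record/line
        raise ValueError(f"malformed {format} in {path}: {exc}") from exc
    return records


def write_fasta(seqs: Iterable[NucleotideSequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}" + (f" {s.description}" if s.description else "") + "\n")
            for i in range(0, len(s.residues), 70):
                fh.write(s.residues[i : i + 70] + "\n")


def write_fastq(seqs: Iterable[NucleotideSequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            qual = s.quality or "I" * len(s.residues)
            desc = f" {s.description}" if s.description else ""
            fh.write(f"@{s.id}{desc}\n{s.residues}\n+\n{qual}\n")


_GFF_ESCAPE = {";": "%3B", "=": "%3D", "&": "%26", ",": "%2C", "%": "%25"}


def _escape(value: str) -> str:
    value = value.replace("%", "%25")
    for char, code in _GFF_ESCAPE.items():
        if char != "%":
            value = value.replace(char, code)
    return value


def _unescape(value: str) -> str:
    for char, code in _GFF_ESCAPE.items():
        value = value.replace(code, char)
    return value


def write_features(
    annotation: list[Feature], sequence: NucleotideSequence, path: str | Path
) -> None:
    """Write features as GFF3; validates every feature against the sequence."""
    n = len(sequence.residues)
    for feat in annotation:
        if feat.end > n:
            raise ValueError(
                f"feature {feat.kind.value} {feat.start}..{feat.end} exceeds "
                f"sequence length {n}"
            )
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {sequence.id} 1 {n}\n")
        for feat in annotation:
            attrs = {"kind": feat.kind.value, **feat.attributes}
            attr_col = ";".join(f"{_escape(k)}={_escape(v)}" for k, v in attrs.items())
            score = "." if feat.score is None else f"{feat.score:g}"
            fh.write(
                "\t".join(
                    [
                        sequence.id,
                        "ambidense",
                        _SO_TYPE[feat.kind],
                        str(feat.start),
                        str(feat.end),
                        score,
                        feat.strand,
                        ".",
                        attr_col or ".",
                    ]
                )
                + "\n"
            )


def read_features(path: str | Path) -> list[Feature]:
    """Read back a GFF3 file written by :func:`write_features`."""
    feats: list[Feature] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            attributes: dict[str, str] = {}
            if cols[8] != ".":
                for pair in cols[8].split(";"):
                    key, _, val = pair.partition("=")
                    attributes[_unescape(key)] = _unescape(val)
            kind = FeatureKind(attributes.pop("kind"))
            feats.append(
                Feature(
                    kind=kind,
                    start=int(cols[3]),
                    end=int(cols[4]),
                    strand=cols[6],
                    score=None if cols[5] == "." else float(cols[5]),
                    attributes=attributes,
                )
            )
    return feats
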