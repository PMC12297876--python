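# Methods

This note records the models, parameter choices, numerical conventions and
known limitations behind each stage of the package.

## Coordinate and sequence conventions

All coordinates are 1-based, fully inclusive, and expressed on the forward
strand, including features on the minus strand (a reverse-strand start
codon is reported by its forward-strand interval). Protein lengths exclude
the stop codon, so an ORF spanning *n* coding nucleotides plus a stop
yields exactly *n*/3 residues. Readers degrade IUPAC ambiguity codes to N
with a warning rather than erroring, because field data contain them; the
simulator itself never emits them.

## Synthetic genome generator

The generator is the package's study system: it builds genomes with the
canonical homotelomeric ambisense architecture and a complete ground-truth
ledger, so every detector can be tested by parameter recovery.

**Geometry.** A perfect ITR forces mirror symmetry — base *i* equals the
complement of base *L*+1−*i* within the terminal repeats — so the
generator plants the 5' elements and derives the 3' ones. The terminal
`terminal_repeat_length` (default 107 nt) region is built column-wise: arm
columns are self-complementary (palindromic), so the two termini read as
direct repeats there; the central `flipflop_length` (default 55 nt)
segment carries non-palindromic columns at its outermost positions and at
the centre, which is exactly what makes "flip" and "flop" distinguishable
while both termini still fold into the same hairpin. A handful of bases
flanking these bubbles and the hairpin loop are pinned to strong pairs so
that the fold optimum is unique: otherwise the maximum-weight structure is
tie-degenerate and the two windows can fold asymmetrically. One
consequence of the mirror symmetry is worth stating: the ITR TATA box
planted at 93–98 on the plus strand necessarily reappears as a
minus-strand TATA in the 3' ITR at the mirrored interval; the two ITR TATA
boxes of a perfect-ITR genome cannot be placed independently.

**Coding blocks.** ORFs are built codon-first from the sense-codon
alphabet, so protein lengths are exact by construction. The NS region
sampler simultaneously satisfies: the NS2 AUG is the first AUG after the
NS1 AUG (an upstream in-frame stop pins NS2's reported start); the NS2
frame is stop-free through its planted length; the HuH (H-V-H, aa
256–258) and YuxK (Y-I-Q-K, aa 307–310) nickase motifs are encoded at
their canonical NS1 positions; and the NS1→NS2 leader contains no AUG in
any frame (the leaky-scanning condition). The VP block is sampled in
mRNA sense and placed as its reverse complement, carrying the internal
TATA-like element, the truncated-VP start codon (in frame with VP, sharing
its stop), and the diagnostic-PCR primer sites. Chance open frames ≥ 100
codons elsewhere are removed by recoding one unconstrained codon to plant
a stop in the offending frame; residual conflicts are handled by
regenerating with a fresh substream. The finished genome is accepted only
after the package's own detectors recover every planted value exactly
(generator–detector closure).

**Defaults.** All architectural defaults equal the natural geometry of the
whitefly ambidensovirus this package was built around: total length
5123 nt, ITR 207 nt, terminal repeat 107 nt, flip-flop 55 nt, NS1 719 aa,
NS2 332 aa, VP 749 aa, truncated VP 435 aa, three leader uAUGs, a single
372 bp diagnostic amplicon, one G-quadruplex tract per telomere flanking
the hairpin.

## Read simulation

Reads (default 2 × 150 nt geometry, unpaired by default) are drawn from
both genome strands with uniform start positions, except that fragments
overlapping either ITR are down-weighted by `terminal_decay` (default
0.2) — terminal hairpins amplify and sequence poorly, and published
densovirus assemblies show their lowest coverage at the extreme termini.
The decay shape is a free modelling choice (a single multiplicative
factor); real decay profiles are not published. Because a linear genome is
fragmented, read starts may precede position 1 and reads are clipped (to
≥ 30 nt) at the termini; without this, uniform internal starts would give
the outermost bases near-zero coverage and no read set could ever complete
a genome. Haplotype alternates are emitted per site at their stated
frequencies (sites are unlinked in this model), substitution errors are
i.i.d., and no indel or quality-dependent error model is included. Host
contamination draws uniform reads from a supplied host sequence. A fixed
seed yields byte-identical FASTQ output.

## Host filtering and enrichment

Host subtraction is a canonical k-mer membership filter (k = 31, removal
when more than half of a read's k-mers occur in the host index). This
replaces read mapping against host references with an exactly reproducible
in-repo equivalent of the same intent; reads shorter than k are kept with
a warning, and paired mates are filtered independently. Redundant-read
enrichment collapses exact duplicates only — mismatch-tolerant clustering
would blur the "unique sequences represented by ≥ N reads" semantics.

## Terminal extension

Mapping is exact-seed (15-mers at several read offsets) plus ungapped
extension with a 5% mismatch budget and a 30 nt minimum anchor; the error
model is substitution-only, matching the simulator, so no gapped extension
is attempted. Two deliberate choices deal with the telomere geometry:

* Reads lying entirely inside a perfect ITR match both termini with zero
  mismatches. The leftmost placement is kept as primary, but equally good
  alternate placements are retained as secondary alignment records —
  dropping them would starve the 3' terminus of both coverage and
  overhang evidence (the depth vector counts alignments, so the
  per-base-depth invariant is preserved; multi-mapped telomeric reads
  contribute to both ITRs' depth, as they should).
* Overhang consensus uses only alignments with mismatch-free anchors.
  Short terminally-clipped reads can be placed on the mirror register of
  the quasi-palindromic hairpin within the mismatch budget, and their
  overhangs would vote the flop orientation into the flip consensus; any
  such mis-placement carries at least one anchor mismatch (every ≥ 30 nt
  hairpin window covers a distinguishing column), so the filter excludes
  exactly the poisoned evidence.

Extension itself is column-majority consensus moving outward: a column is
adopted iff covered by ≥ 3 overhangs with modal frequency ≥ 0.8; the
first failing column stops the walk (ambiguity stops extension rather
than emitting IUPAC codes — a hard stop fails safe). Completion
alternates mapping and two-sided extension until stable, never edits
existing contig bases, and re-maps at the end; the result is flagged
COMPLETE only when every base is covered by at least the support
threshold, so a byte-exact genome can still be flagged PARTIAL when
decayed telomeric coverage dips below 3× at single positions.

**Identifiability limit.** Flip/flop assignment of terminal reads relies
on each anchor covering at least one distinguishing (non-palindromic)
column. If any palindromic column run of the hairpin — the arms, or the
two interior halves of the flip-flop segment — is at least as long as the
mapping anchor (30 nt), mirror-register placements inside that run are
mismatch-free: their overhangs carry the reflected sequence, which can
stall extension at distinguishing columns or walk past the true terminus
into phantom sequence. The natural geometry (26 nt arms, 25 nt interior
half-runs) is identifiable, and the random-spec test harness stays within
that regime (arms ≤ 29, flip-flop ≤ 61 nt); wider palindromic runs are a
documented limitation of short-read terminal assembly, not of this
implementation specifically.

## Telomere analysis

*ITR detection* finds the maximal n whose prefix differs from the
reverse-complemented suffix at no more than `max_mismatch` positions
(default 0; the parameter exists because terminal repeats may be called
"perfect" at the repeat level yet imperfect at the palindrome level).

*Flip-flop detection* compares the terminal windows as direct repeats.
Under a perfect ITR the 3' window is exactly the reverse complement of the
5' window, so directly matching columns are precisely the palindromic
columns, and the inversion is recovered as the minimal centred segment
covering all direct mismatches, validated by ≥ 90% inverted-segment
identity and requiring at least 12 directly matching flank columns per
side (the shortest plausible hairpin arm; this rejects spuriously shifted
windows). Auto mode searches window lengths 50–300 and keeps the
best-supported one.

*Hairpin folding* is a maximum-weight nested-pairing dynamic program with
weights G·C = 3, A·T = 2, G·T = 1 and a minimum loop of three unpaired
bases, with a deterministic traceback. It is a topology/symmetry tool: the
scores are weighted pair counts, not free energies, and no thermodynamic
claims are made — only structural identity of the two telomeres is
asserted.

*G-quadruplex scanning* enumerates quadruplets of equal-length G-runs
(runs ≥ 2, total span ≤ 45 nt, loops 0–36 nt) on both strands and scores
them in the style of G-rich-sequence mappers — longer G-runs, shorter and
more equal loops score higher (score = 20·(run−2) + loop-balance +
compactness terms); overlapping candidates reduce to the best per locus.
The exact score scale is this package's own; only relative ranking and
hit geometry are meaningful.

## Transcription map

ORFs are AUG-to-stop on all six frames with the first-AUG-after-stop
convention, so nested same-frame starts are subsumed while nested ORFs in
other frames (NS2 inside NS1) are retained. Cis-elements are exact-match
scans for TATAAA, TAAATAAA and AATAAA on both strands; fuzzy promoter
matching is deliberately rejected to keep outputs decidable. The TSS is
predicted 32 nt downstream of a promoter element's start — the spacing
consistent with the observed TATA-like → TSS distance in these viruses.
Unit assembly: the largest forward ORF is NS1 with the nearest upstream
TAAATAAA as promoter and first downstream AATAAA as terminator; the
largest reverse ORF is VP with the closest minus-strand ITR TATA as
promoter; the minus-strand TAAATAAA inside the VP ORF is nominated as a
putative internal promoter, and the first AUG downstream of its predicted
TSS defines the truncated VP, which must share VP's reading frame (a
frame mismatch demotes the prediction to a warning). Leaky scanning for
NS2 is assessed purely from AUG positions: plausible iff no AUG occurs
between the NS1 and NS2 start codons. HuH/YuxK motifs are matched as
H-Φ-H and Y-Φ-x-K (Φ hydrophobic); because isolated chance matches are
common in 700-residue proteins, the nickase call is the first *pair* with
the characteristic 40–70 aa spacing. Protein-domain calls (PLA2,
Denso_VP4, SF3, Parvo NS1) are carried as external sidecar annotations,
not recomputed.

## In silico PCR

All forward-site × reverse-site combinations within the length bound on
both template orientations are reported; internal mismatches up to the
primer pair's budget are tolerated but the 3'-terminal base must match
exactly (polymerase extension from a mismatched 3' end is inefficient).
Multiple products are all reported, since field samples can yield
off-sized products. The specificity verdict requires zero amplicons in
every non-target genome.

## EVE scanning

Local alignment is seeded (exact 11-mers clustered by diagonal) affine-gap
Smith–Waterman, megablast-like scoring (match +2, mismatch −3, gap of
length g costs 5 + 2g); small problems run the full dynamic program.
Percent identity is computed over all alignment columns with gaps in the
denominator. Tandem arrays chain collinear same-strand hits whose
inter-copy gap is under 20% of the unit length; singletons are arrays of
copy number one, and an inverted copy breaks the chain. Splice-fusion
reconstruction enumerates GT donors inside the integrant and AG acceptors
downstream (intron length 60–5000 nt by default), splices in silico, and
keeps ORFs that start at an AUG inside the integrant, cross the junction,
and terminate; candidates rank by spliced-ORF length. Only canonical
GT..AG junctions are considered and no splice-site strength model is
applied. Minus-strand integrants must currently be rescanned on the
reverse-complemented scaffold.

The fusion-locus builder reproduces the canonical neofunctionalization
architecture at its published proportions (1271 nt intron, 486 aa fusion):
a viral segment degraded to the requested identity with its NS1 frame
preserved up to the donor, an AG-free intron, and a host exon. The intron
interior and downstream tail are interleaved with stop blocks in all
three frames so that the planted junction is the unique longest-ORF
solution — the identifiability this models is real (the genuine locus has
a unique productive junction), but the sequence outside the planted
elements is synthetic and deliberately ORF-poor.

## What the synthetic data do and do not show

Passing the recovery suites demonstrates that the algorithms are correct
under their stated models: substitution-only errors, exact planted
identities, unlinked haplotype sites, single-factor terminal decay, and
uniquely identifiable flip-flop and splice-junction geometries. Real data
add indels, quality-correlated errors, RCA chimeras and concatemers,
linked haplotypes, diverged multi-copy EVEs with internal rearrangements,
and assemblies with gaps — none of which are simulated. Results on real
libraries should therefore be validated by the re-mapping report
(coverage and mismatch profiles) that the completion stage emits.

## Reported problem sizes

The acceptance script measures the full battery on one reference-scale
genome (5123 nt), twenty random-geometry recovery runs at 30× simulated
coverage with 40–80 nt truncations, planted-integrant scans over 6–8 kb
scaffolds, a 29-copy (~32 kb) tandem array, and one fusion locus; these
sizes keep a complete replication run under a minute on a single CPU
while exercising every code path at realistic scale.
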