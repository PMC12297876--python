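#!/usr/bin/env python
"""Diagnostic in silico PCR: amplicon prediction and specificity screen.

Runs the VP-gene primer pair against the viral genome (expected single
372 bp product) and against synthetic host scaffolds with and without
VP-region integrants (expected negative / positive), writing a TSV.
"""

from pathlib import Path

from ambidense.epcr import PrimerPair, in_silico_pcr, primer_uniqueness
from ambidense.simulate import (
    PRIMER_FWD,
    PRIMER_REV,
    GenomeSpec,
    build_ambisense_genome,
    plant_eve_locus,
    random_host,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 1


def main() -> None:
    truth = build_ambisense_genome(GenomeSpec(seed=SEED))
    pair = PrimerPair(PRIMER_FWD, PRIMER_REV)
    amps = in_silico_pcr(truth.genome, pair)
    print(f"viral genome: {len(amps)} amplicon(s): "
          + ", ".join(f"{a.length} bp at {a.start}-{a.end}" for a in amps))

    host_ns = random_host(20000, seed=SEED + 1, ident="host_with_NS_eve")
    host_ns, truth = plant_eve_locus(
        host_ns, truth, (41, 1597), identity=0.8, copies=1, seed=SEED + 2
    )
    host_vp = random_host(20000, seed=SEED + 3, ident="host_with_VP_eve")
    host_vp, truth = plant_eve_locus(
        host_vp, truth, (2655, 4904), identity=1.0, copies=1, seed=SEED + 4
    )
    genomes = [truth.genome, host_ns, host_vp]
    rows, _ = primer_uniqueness(pair, genomes, target_id=truth.genome.id)
    _, specific_wo_vp = primer_uniqueness(
        pair, [truth.genome, host_ns], target_id=truth.genome.id
    )
    RESULTS.mkdir(exist_ok=True)
    with open(RESULTS / "epcr.tsv", "w") as fh:
        fh.write("genome\tforward_sites\treverse_sites\tamplicons\n")
        for r in rows:
            fh.write(f"{r.genome_id}\t{r.forward_sites}\t{r.reverse_sites}"
                     f"\t{r.amplicons}\n")
            print(f"{r.genome_id}: {r.amplicons} amplicon(s)")
    print(f"assay specific against the NS-integrant host: {specific_wo_vp}")
    print(f"-> {RESULTS}/epcr.tsv")


if __name__ == "__main__":
    main()
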