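#!/usr/bin/env python
"""Endogenous viral element scan: integrants, tandem arrays, splice fusion.

Plants integrants at several identities, a 29-copy head-to-tail array of
the ~1.1 kb Rep nickase region, and a fusion locus whose viral reading
frame splices (GT..AG, 1271 nt intron) onto a downstream host exon to
encode a 486 aa Rep-host fusion protein; then recovers all of them with
the scanning machinery.  Writes hit and array tables under results/.
"""

from pathlib import Path

from ambidense.evescan import (
    attach_segments,
    detect_tandem_array,
    find_splice_fusion,
    scan_host_for_eves,
)
from ambidense.simulate import (
    GenomeSpec,
    build_ambisense_genome,
    build_rep_fusion_locus,
    plant_eve_locus,
    random_host,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 1


def main() -> None:
    truth = build_ambisense_genome(GenomeSpec(seed=SEED))
    genome = truth.genome
    rows = []

    host = random_host(12000, seed=SEED + 10, ident="scaffold_single")
    host, truth = plant_eve_locus(
        host, truth, (41, 1597), identity=0.75, copies=1, seed=SEED + 11
    )
    hits = scan_host_for_eves(genome, [host], annotation=truth.features)
    for h in hits:
        rows.append(h)
        print(f"{h.scaffold}: viral {h.viral_start}-{h.viral_end} at "
              f"{100*h.identity:.1f}% identity, spans {h.label}")

    host2 = random_host(8000, seed=SEED + 12, ident="scaffold_array")
    host2, truth = plant_eve_locus(
        host2, truth, (437, 1537), identity=0.75, copies=29, seed=SEED + 13
    )
    hits2 = scan_host_for_eves(genome, [host2])
    attach_segments(hits2, [host2])
    rows.extend(hits2)
    (array,) = detect_tandem_array(hits2)
    print(f"{host2.id}: {array.copy_number} head-to-tail copies of "
          f"~{array.unit_length} nt, inter-copy identity "
          f"{100*array.mean_inter_copy_identity:.1f}%")

    scaffold, info = build_rep_fusion_locus(truth, seed=SEED + 14)
    fhits = scan_host_for_eves(genome, [scaffold])
    rows.extend(fhits)
    cands = find_splice_fusion(scaffold, fhits[0])
    top = cands[0]
    print(f"{scaffold.id}: fusion ORF of {top.aa_length} aa over a "
          f"{top.intron_length} nt GT..AG intron (donor {top.donor}, "
          f"acceptor {top.acceptor}); viral exon {top.viral_segment_nt} nt, "
          f"host exon {top.host_segment_nt} nt")

    RESULTS.mkdir(exist_ok=True)
    with open(RESULTS / "eve_hits.tsv", "w") as fh:
        fh.write("scaffold\thost_start\thost_end\tviral_start\tviral_end"
                 "\tstrand\tidentity\tlength\tlabel\n")
        for h in rows:
            fh.write(f"{h.scaffold}\t{h.host_start}\t{h.host_end}"
                     f"\t{h.viral_start}\t{h.viral_end}\t{h.strand}"
                     f"\t{h.identity:.4f}\t{h.length}\t{h.label}\n")
    print(f"-> {RESULTS}/eve_hits.tsv")


if __name__ == "__main__":
    main()
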