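#!/usr/bin/env python
"""Ambisense transcription map: ORFs, cis-elements, leaky scanning, motifs.

Builds the converging NS (rightward) / VP (leftward) transcription map,
reports the leaky-scanning assessment for NS2, the internal-promoter
prediction of the N-terminally truncated VP, and the NS1 nickase motifs.
Writes the map as JSON under results/.
"""

import json
from pathlib import Path

from ambidense.annotate import (
    build_transcription_map,
    find_orfs,
    nickase_motif_pair,
    scan_cis_elements,
)
from ambidense.simulate import GenomeSpec, build_ambisense_genome

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 1


def main() -> None:
    truth = build_ambisense_genome(GenomeSpec(seed=SEED))
    genome = truth.genome
    orfs = find_orfs(genome)
    cis = scan_cis_elements(genome)
    tmap = build_transcription_map(genome, orfs, cis)
    ns1 = tmap.ns_unit.orfs[0]
    pair = nickase_motif_pair(ns1.protein)
    report = {
        "orfs": [
            {"start": o.feature.start, "end": o.feature.end,
             "strand": o.strand, "aa": o.aa_length}
            for o in orfs
        ],
        "ns_unit": {
            "promoter": [tmap.ns_unit.promoter.start, tmap.ns_unit.promoter.end],
            "outer_itr_tata": [tmap.ns_unit.outer_promoter.start,
                               tmap.ns_unit.outer_promoter.end],
            "tss": tmap.ns_unit.tss.start,
            "polya": tmap.ns_unit.polya.start,
            "leader_uaugs": tmap.ns_unit.leader_uaug_count,
        },
        "vp_unit": {
            "promoter": [tmap.vp_unit.promoter.start, tmap.vp_unit.promoter.end],
            "polya": tmap.vp_unit.polya.start,
            "leader_uaugs": tmap.vp_unit.leader_uaug_count,
        },
        "leaky_scanning": {
            "intervening_augs": tmap.leaky_scan.intervening_aug_count,
            "verdict": tmap.leaky_scan.verdict,
        },
        "truncated_vp": {
            "internal_promoter": [tmap.truncated_vp.internal_promoter.start,
                                  tmap.truncated_vp.internal_promoter.end],
            "start_codon": list(tmap.truncated_vp.start_interval),
            "aa": tmap.truncated_vp.aa_length,
            "in_frame_with_vp": tmap.truncated_vp.in_frame_with_vp,
        },
        "ns1_nickase_motifs": {"HuH": pair[0], "YuxK": pair[1]},
    }
    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "transcription_map.json").write_text(json.dumps(report, indent=2))
    print(json.dumps(report, indent=2))
    print(f"-> {RESULTS}/transcription_map.json")


if __name__ == "__main__":
    main()
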