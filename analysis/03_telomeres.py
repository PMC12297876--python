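#!/usr/bin/env python
"""Telomere analysis: ITRs, flip-flop repeats, hairpin folds, G4 elements.

Detects the inverted terminal repeats, the terminal direct repeats with
their internal flip-flop inversion, folds both hairpin regions (expected
to produce identical structures) and scans for G-quadruplex candidates
flanking the hairpins.  Writes a text report under results/.
"""

from pathlib import Path

from ambidense.simulate import GenomeSpec, build_ambisense_genome
from ambidense.telomere import (
    detect_flip_flop,
    detect_itr,
    fold_hairpin,
    scan_g_quadruplex,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 1


def main() -> None:
    truth = build_ambisense_genome(GenomeSpec(seed=SEED))
    genome = truth.genome
    s = genome.residues
    lines = []
    itr = detect_itr(genome)
    lines.append(f"ITR: {itr.length} nt, {itr.mismatches} mismatches "
                 f"({itr.left[0]}-{itr.left[1]} / {itr.right[0]}-{itr.right[1]})")
    ff = detect_flip_flop(genome)
    lines.append(
        f"terminal repeats: {ff.repeat_length} nt direct repeats, "
        f"{ff.inversion_length} nt internal inversion at "
        f"{ff.inversion[0]}-{ff.inversion[1]} ({ff.relation})"
    )
    f5 = fold_hairpin(s[: ff.repeat_length])
    f3 = fold_hairpin(s[-ff.repeat_length :])
    lines.append(f"5' hairpin ({f5.score}): {f5.structure}")
    lines.append(f"3' hairpin ({f3.score}): {f3.structure}")
    lines.append(f"structures identical: {f5.structure == f3.structure}")
    hits = [
        h for h in scan_g_quadruplex(genome)
        if h.start <= itr.length or h.end > len(s) - itr.length
    ]
    for h in hits:
        lines.append(
            f"G4 {h.start}-{h.end} ({h.strand}) runs of {h.g_run_length} G, "
            f"loops {h.loops}, score {h.qgrs_score}"
        )
    report = "\n".join(lines) + "\n"
    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "telomere_report.txt").write_text(report)
    print(report, end="")
    print(f"-> {RESULTS}/telomere_report.txt")


if __name__ == "__main__":
    main()
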