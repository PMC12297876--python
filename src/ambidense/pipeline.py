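"""End-to-end orchestration: filter -> enrich -> complete -> annotate.

A single structured config drives every stage with the same defaults the
stage functions use; identical config plus seed yields byte-identical
outputs.  Each stage's parameters, inputs and outputs are logged with ISO
timestamps, and a machine-readable run summary is written as JSON.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path

from . import annotate as _annotate
from . import epcr as _epcr
from . import evescan as _evescan
from . import readfilter as _readfilter
from . import simulate as _simulate
from . import telomere as _telomere
from .core import (
    Feature,
    FeatureKind,
    NucleotideSequence,
    load_sequences,
    write_fasta,
    write_fastq,
    write_features,
)
from .extend import complete_genome, coverage_report

logger = logging.getLogger("ambidense")

_STAGES = ("filter", "enrich", "extend", "telomere", "annotate", "epcr", "evescan")


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "ambidense_out"
    # inputs: either simulate=True or provide contig/reads paths
    simulate: bool = True
    contig_fasta: str | None = None
    reads_fastq: str | None = None
    host_fasta: str | None = None
    truncate: tuple[int, int] = (60, 60)
    stages: dict = field(
        default_factory=lambda: {name: True for name in _STAGES}
    )
    genome: dict = field(default_factory=dict)  # GenomeSpec overrides
    reads: dict = field(default_factory=dict)  # ReadSimParams overrides
    filter_params: dict = field(default_factory=lambda: {"k": 31, "max_host_fraction": 0.5})
    enrich_params: dict = field(default_factory=lambda: {"min_count": 10})
    extend_params: dict = field(default_factory=dict)
    epcr_params: dict = field(
        default_factory=lambda: {
            "forward": _simulate.PRIMER_FWD,
            "reverse": _simulate.PRIMER_REV,
            "max_len": 5000,
        }
    )
    evescan_params: dict = field(
        default_factory=lambda: {"min_identity": 0.65, "min_length": 200}
    )

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**{k: v for k, v in data.items() if k in known})
        if isinstance(cfg.truncate, list):
            cfg.truncate = tuple(cfg.truncate)
        bad_stage = set(cfg.stages) - set(_STAGES)
        if bad_stage:
            raise ValueError(f"unknown stages: {sorted(bad_stage)}")
        merged = {name: True for name in _STAGES}
        merged.update(cfg.stages)
        cfg.stages = merged
        return cfg

    def validate(self) -> None:
        if not any(self.stages.values()):
            raise ValueError("all stages are switched off; nothing to run")
        if not self.simulate:
            if self.contig_fasta is None or self.reads_fastq is None:
                raise ValueError(
                    "contig_fasta and reads_fastq are required when simulate=False"
                )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns a summary dict (also written
    to ``<out_dir>/run_summary.json``)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "log.txt"
    log_lines: list[str] = []

    def log(msg: str) -> None:
        stamp = datetime.now(timezone.utc).isoformat(timespec="seconds")
        log_lines.append(f"{stamp} {msg}")
        logger.info(msg)

    summary: dict = {"seed": config.seed, "stages": {}}
    log(f"effective config: {json.dumps(asdict(config), default=str, sort_keys=True)}")

    truth = None
    host = None
    if config.host_fasta:
        host = load_sequences(config.host_fasta)[0]
    if config.simulate:
        spec = _simulate.GenomeSpec(**{**config.genome, "seed": config.seed})
        truth = _simulate.build_ambisense_genome(spec)
        params = _simulate.ReadSimParams(**{**config.reads, "seed": config.seed})
        reads = _simulate.simulate_rca_reads(truth, params, host)
        lcut, rcut = config.truncate
        g = truth.genome.residues
        contig = NucleotideSequence(
            id="contig", residues=g[lcut : len(g) - rcut]
        )
        _simulate.write_truth(truth, out / "truth")
        write_fastq(reads, out / "reads.fastq")
        log(f"simulate: genome {len(g)} nt, {len(reads)} reads, "
            f"contig truncated by {lcut}/{rcut}")
        summary["stages"]["simulate"] = {
            "genome_length": len(g),
            "n_reads": len(reads),
        }
    else:
        contig = load_sequences(config.contig_fasta)[0]
        reads = load_sequences(config.reads_fastq, "fastq")
        log(f"inputs: contig {len(contig.residues)} nt, {len(reads)} reads")

    if config.stages["filter"] and host is not None:
        p = config.filter_params
        index = _readfilter.KmerIndex.build([host], k=p.get("k", 31))
        kept, removed = _readfilter.host_filter(
            reads, index, p.get("max_host_fraction", 0.5)
        )
        (out / "removed_reads.txt").write_text(
            "".join(r.id + "\n" for r in removed)
        )
        log(f"filter: kept {len(kept)}, removed {len(removed)} host-like reads")
        summary["stages"]["filter"] = {"kept": len(kept), "removed": len(removed)}
        reads = kept

    if config.stages["enrich"]:
        mc = config.enrich_params.get("min_count", 10)
        redundant = _readfilter.enrich_redundant(reads, mc)
        log(f"enrich: {len(redundant)} unique sequences at count >= {mc}")
        summary["stages"]["enrich"] = {"redundant_uniques": len(redundant)}

    genome = contig
    if config.stages["extend"]:
        res = complete_genome(contig, reads, **config.extend_params)
        genome = res.genome
        write_fasta([genome], out / "completed_genome.fasta")
        cov = coverage_report(res.pile)
        log(
            f"extend: {res.status} after {len(res.rounds)} rounds, "
            f"{len(genome.residues)} nt, depth {cov.min_depth}-{cov.max_depth}"
        )
        summary["stages"]["extend"] = {
            "status": res.status,
            "length": len(genome.residues),
            "rounds": [dataclasses.asdict(r) for r in res.rounds],
        }

    features: list[Feature] = []
    if config.stages["telomere"]:
        itr = _telomere.detect_itr(genome)
        ff = _telomere.detect_flip_flop(genome)
        g4s = _telomere.scan_g_quadruplex(genome)
        tel_summary = {
            "itr_length": itr.length if itr else None,
            "repeat_length": ff.repeat_length,
            "inversion_length": ff.inversion_length,
            "g4_hits": len(g4s),
        }
        if itr:
            features.append(Feature(FeatureKind.ITR5, *itr.left, "+"))
            features.append(Feature(FeatureKind.ITR3, *itr.right, "-"))
            fold = _telomere.fold_hairpin(
                genome.residues[: ff.repeat_length or itr.length]
            )
            (out / "hairpin.txt").write_text(
                genome.residues[: len(fold.structure)] + "\n" + fold.structure + "\n"
            )
            tel_summary["hairpin_score"] = fold.score
        if ff.inversion:
            features.append(
                Feature(FeatureKind.FLIPFLOP, *ff.inversion, "+",
                        attributes={"repeat_length": str(ff.repeat_length)})
            )
        for h in g4s:
            features.append(
                Feature(FeatureKind.G4, h.start, h.end, h.strand, score=h.qgrs_score)
            )
        log(f"telomere: {tel_summary}")
        summary["stages"]["telomere"] = tel_summary

    if config.stages["annotate"]:
        orfs = _annotate.find_orfs(genome)
        cis = _annotate.scan_cis_elements(genome)
        tmap = _annotate.build_transcription_map(genome, orfs, cis)
        for o in orfs:
            features.append(o.feature)
        features.extend(cis)
        ns1 = tmap.ns_unit.orfs[0]
        motifs = _annotate.scan_protein_motifs(ns1.protein)
        with open(out / "proteins.fasta", "w") as fh:
            for o in orfs:
                fh.write(f">{o.protein.id} {o.aa_length}aa\n{o.protein.residues}\n")
        ann_summary = {
            "orfs": [
                {"start": o.feature.start, "end": o.feature.end,
                 "strand": o.strand, "aa": o.aa_length}
                for o in orfs
            ],
            "leader_uaugs": tmap.ns_unit.leader_uaug_count,
            "leaky_scan": tmap.leaky_scan.verdict,
            "truncated_vp_aa": tmap.truncated_vp.aa_length if tmap.truncated_vp else None,
            "ns1_motifs": [
                {"name": f.attributes["name"], "start": f.start}
                for f in motifs
            ],
        }
        log(f"annotate: {len(orfs)} ORFs, leaky scanning {tmap.leaky_scan.verdict}")
        summary["stages"]["annotate"] = ann_summary

    if config.stages["epcr"]:
        p = config.epcr_params
        pair = _epcr.PrimerPair(p["forward"], p["reverse"], p.get("max_mismatch", 0))
        amps = _epcr.in_silico_pcr(genome, pair, p.get("max_len", 5000))
        for a in amps:
            features.append(
                Feature(FeatureKind.PRIMER_SITE, a.start, a.end, "+",
                        attributes={"length": str(a.length)})
            )
        log(f"epcr: {len(amps)} amplicon(s) "
            + ", ".join(str(a.length) + " bp" for a in amps))
        summary["stages"]["epcr"] = {
            "amplicons": [{"start": a.start, "end": a.end, "length": a.length}
                          for a in amps]
        }

    if config.stages["evescan"] and host is not None:
        p = config.evescan_params
        hits = _evescan.scan_host_for_eves(
            genome, [host],
            min_identity=p.get("min_identity", 0.65),
            min_length=p.get("min_length", 200),
        )
        arrays = _evescan.detect_tandem_array(hits)
        with open(out / "eve_hits.tsv", "w") as fh:
            fh.write("scaffold\thost_start\thost_end\tviral_start\tviral_end"
                     "\tstrand\tidentity\tlength\n")
            for h in hits:
                fh.write(
                    f"{h.scaffold}\t{h.host_start}\t{h.host_end}\t{h.viral_start}"
                    f"\t{h.viral_end}\t{h.strand}\t{h.identity:.4f}\t{h.length}\n"
                )
        log(f"evescan: {len(hits)} hits in {len(arrays)} array(s)")
        summary["stages"]["evescan"] = {
            "hits": len(hits),
            "arrays": [
                {"copies": a.copy_number, "unit": a.unit_length} for a in arrays
            ],
        }

    if features:
        features.sort(key=lambda f: (f.start, f.kind.value))
        write_features(features, genome, out / "features.gff3")
    log_path.write_text("\n".join(log_lines) + "\n")
    (out / "run_summary.json").write_text(json.dumps(summary, indent=2))
    return summary
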