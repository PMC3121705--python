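"""Full-genome characterization pipeline and report assembly.

``run_pipeline`` chains the modules the way a phage genome paper's Results
section is organized: general features, ORFs, regulatory elements, codon
usage vs host, proteome properties and holin screen, proteome comparison,
and host-range phenotyping — each stage optional per the config, each
section present in the report or explicitly marked skipped with the reason.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Any, Optional

import pandas as pd

from . import codon_usage, comparative, genome_io, host_range, orf_caller, proteomics, regulatory
from .model import AnnotatedGenome

logger = logging.getLogger("phagecharm")

#: Defaults follow the characterization protocol's stated values.
DEFAULT_CONFIG = {
    "annotation": "trust",          # trust | recall
    "min_extra_codons": 30,
    "rbs_motif": "GGAGGT",
    "rbs_min_score": 4,
    "rbs_window": [4, 16],
    "sigma70_box35": "TTGACA",
    "sigma70_box10": "TATAAT",
    "sigma70_spacer": [15, 18],
    "sigma70_max_mismatch": 1,
    "late_motif": "TATAAATA",
    "late_max_mismatch": 1,
    "terminator_dg_max": -10.0,
    "terminator_intergenic": True,
    "delta_od": 0.3,
    "dplus_hours": 5.0,
    "codon_freq_min": 0.30,
    "codon_fold_min": 1.5,
    "holin_max_len": 130,
    "band_tolerance_kda": 8.0,
    "rbh_score_min": 75.0,
}


@dataclass
class GenomeReport:
    genome_id: str
    stats: Optional[dict] = None
    orfs: list = field(default_factory=list)
    promoters: dict = field(default_factory=dict)
    terminators: list = field(default_factory=list)
    codon_comparison: list = field(default_factory=list)
    proteome: list = field(default_factory=list)
    tm_candidates: list = field(default_factory=list)
    comparison: Optional[dict] = None
    host_range: Optional[dict] = None
    skipped: dict = field(default_factory=dict)  # section -> reason
    parameters: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        def plain(obj: Any) -> Any:
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: plain(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            if isinstance(obj, float) and obj != obj:  # NaN
                return None
            return obj
        return plain(dataclasses.asdict(self))


def _load_genome(path: str) -> AnnotatedGenome:
    if str(path).endswith((".fa", ".fasta", ".fna")):
        return genome_io.read_fasta(path)
    return genome_io.read_genbank(path)


def _proteome_from_genome(genome: AnnotatedGenome) -> dict[str, str]:
    """locus -> translation for every CDS carrying (or yielding) one."""
    from Bio.Seq import Seq
    prot = {}
    for f in genome.cds:
        if f.translation:
            prot[f.locus_tag] = f.translation
        else:
            nt = f.extract(genome.sequence)
            if len(nt) % 3 == 0:
                prot[f.locus_tag] = str(Seq(nt).translate(table=11)).rstrip("*")
    return prot


def run_pipeline(config: dict, out_dir: Optional[str] = None) -> GenomeReport:
    """Execute the characterization stages named by ``config``.

    Required key: ``genome`` (GenBank or FASTA path). Optional: ``host_cds``
    (FASTA of host coding sequences), ``compare_genome``, ``plate_csv``,
    ``bands_csv``, ``peptides_csv``. Any stage failure aborts with the stage
    name and cause; completed sections are preserved on the report object
    attached to the raised error.
    """
    cfg = {**DEFAULT_CONFIG, **config}
    if "genome" not in cfg:
        raise ValueError("config must name an input 'genome' before any stage runs")
    report = GenomeReport(genome_id="", parameters={k: cfg[k] for k in DEFAULT_CONFIG})

    def stage(name: str):
        logger.info("stage %s: parameters %s", name,
                    {k: v for k, v in cfg.items() if k in DEFAULT_CONFIG})
        return name

    try:
        stage("genome_io")
        genome = _load_genome(cfg["genome"])
        report.genome_id = genome.id
        if cfg["annotation"] == "recall" or not genome.cds:
            stage("orf_caller")
            cands = orf_caller.find_orfs(
                genome.sequence, cfg["min_extra_codons"],
                rbs_motif=cfg["rbs_motif"], rbs_window=tuple(cfg["rbs_window"]))
            feats = orf_caller.call_genes(cands, cfg["rbs_min_score"])
            genome = AnnotatedGenome(genome.id, genome.sequence, genome.topology,
                                     feats + genome.trnas)
        report.stats = genome_io.genome_summary(genome).as_dict()
        report.orfs = [
            {"locus_tag": f.locus_tag, "start": f.start, "end": f.end,
             "strand": f.strand, **{k: f.qualifiers[k] for k in
                                    ("rbs_score", "start_codon") if k in f.qualifiers}}
            for f in genome.cds
        ]

        stage("regulatory")
        sig = regulatory.scan_bipartite(
            genome.sequence, cfg["sigma70_box35"], cfg["sigma70_box10"],
            cfg["sigma70_spacer"][0], cfg["sigma70_spacer"][1],
            cfg["sigma70_max_mismatch"])
        late = regulatory.scan_fixed_motif(
            genome.sequence, cfg["late_motif"], cfg["late_max_mismatch"])
        report.promoters = {"sigma70": sig, "late": late}
        report.terminators = regulatory.find_terminators(
            genome, cfg["terminator_dg_max"],
            require_intergenic=cfg["terminator_intergenic"] and bool(genome.cds))

        proteome = _proteome_from_genome(genome)
        if proteome:
            stage("proteomics")
            report.proteome = [
                {"locus_tag": t, "length_aa": len(s.rstrip('*')),
                 "mw_kda": proteomics.protein_kda(s),
                 "pi": proteomics.protein_pi(s)}
                for t, s in proteome.items()
            ]
            report.tm_candidates = proteomics.find_tm_candidates(
                proteome, max_len=cfg["holin_max_len"])
        else:
            report.skipped["proteomics"] = "no CDS translations available"

        if cfg.get("host_cds"):
            stage("codon_usage")
            phage_cds = [f.extract(genome.sequence) for f in genome.cds]
            host_cds = list(genome_io.read_fasta_many(cfg["host_cds"]).values())
            report.codon_comparison = codon_usage.overrepresented_codons(
                codon_usage.codon_counts(phage_cds, genome.id),
                codon_usage.codon_counts(host_cds, "host"),
                cfg["codon_freq_min"], cfg["codon_fold_min"])
        else:
            report.skipped["codon_comparison"] = "no host CDS provided"

        if cfg.get("compare_genome"):
            stage("comparative")
            other = _load_genome(cfg["compare_genome"])
            pairs, frac = comparative.shared_homologs(
                proteome, _proteome_from_genome(other), cfg["rbh_score_min"])
            report.comparison = {"n_pairs": len(pairs),
                                 "fraction_of_a_percent": round(frac, 1),
                                 "pairs": pairs}
        else:
            report.skipped["comparison"] = "no comparison genome provided"

        if cfg.get("plate_csv"):
            stage("host_range")
            curves = host_range.read_plate_csv(cfg["plate_csv"])
            calls = host_range.classify_plate(curves, cfg["delta_od"],
                                              cfg["dplus_hours"])
            report.host_range = {"calls": calls,
                                 "summary": host_range.summarize_host_range(calls)}
        else:
            report.skipped["host_range"] = "no plate CSV provided"
    except Exception as exc:
        exc.partial_report = report  # preserve completed sections
        raise

    if out_dir:
        write_report(report, genome, out_dir)
    return report


def write_report(report: GenomeReport, genome: AnnotatedGenome, out_dir: str) -> None:
    """Write report JSON, stats CSV and a GFF3 of called features."""
    os.makedirs(out_dir, exist_ok=True)
    with open(os.path.join(out_dir, "report.json"), "w") as fh:
        json.dump(report.as_dict(), fh, indent=2, sort_keys=True)
    pd.DataFrame([report.stats]).to_csv(os.path.join(out_dir, "stats.csv"), index=False)
    from .model import Feature
    extras = []
    for h in report.promoters.get("sigma70", []):
        extras.append(Feature("promoter", h.start, h.end, h.strand,
                              qualifiers={"score": h.total_mismatches,
                                          "class": "sigma70"}))
    for h in report.promoters.get("late", []):
        extras.append(Feature("promoter", h.position,
                              h.position + len(h.matched_seq), h.strand,
                              qualifiers={"score": h.mismatches, "class": "late"}))
    for t in report.terminators:
        extras.append(Feature("terminator", t.start, t.end, t.strand,
                              qualifiers={"score": t.delta_g}))
    genome_io.write_gff3(genome, os.path.join(out_dir, "features.gff3"), extras)
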