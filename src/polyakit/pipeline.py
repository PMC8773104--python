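"""End-to-end pipeline: read processing -> site calling -> signal analysis
-> APA annotation, with a machine-readable summary.

Every stage is a pure function of (inputs, parameters); the summary JSON
records the per-stage counts (raw, tailed, uniquely mapped, cleavage sites,
clusters), heterogeneity fractions, the PAS frequency table, feature-class
fractions and the APA histogram, plus every parameter used.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import yaml
from Bio import SeqIO

from . import annotation as ann
from . import read_processing as rp
from . import signal_analysis as sig
from . import site_calling as sc
from .errors import ConfigurationError

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    genome_fasta: str = ""
    reads: str = ""                 # FASTQ (RNA-seq) or FASTA (EST)
    est_fasta: Optional[str] = None  # optional second, quality-free stream
    sam: Optional[str] = None        # pre-aligned trimmed reads
    gff3: Optional[str] = None
    outdir: str = "polyakit_out"
    adapter: Optional[str] = None
    min_run: int = rp.DEFAULT_MIN_RUN
    q_threshold: int = rp.DEFAULT_Q_THRESHOLD
    min_fraction: float = rp.DEFAULT_MIN_FRACTION
    min_mappable: int = rp.DEFAULT_MIN_MAPPABLE
    ip_window: int = sc.DEFAULT_IP_WINDOW
    ip_min_run: int = sc.DEFAULT_IP_MIN_RUN
    cluster_gap: int = sc.DEFAULT_CLUSTER_GAP
    flank: int = sig.DEFAULT_FLANK
    pas_window: int = 40
    extension: int = ann.DEFAULT_EXTENSION
    peak_threshold: float = sig.DEFAULT_PEAK_THRESHOLD
    peak_min_total_fraction: float = sig.DEFAULT_MIN_TOTAL_FRACTION
    seed: int = 0

    def validate(self) -> None:
        for name in ("min_run", "q_threshold", "min_mappable", "ip_window",
                     "ip_min_run", "cluster_gap", "flank", "pas_window",
                     "extension"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.pas_window > self.flank:
            raise ConfigurationError(
                f"pas_window ({self.pas_window}) must be <= flank "
                f"({self.flank})"
            )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        cfg.validate()
        return cfg


def load_genome(fasta_path) -> dict[str, str]:
    return {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(str(fasta_path), "fasta")
    }


def _json_default(obj):
    import numpy as np

    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_summary(summary: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True,
                  default=_json_default)
        fh.write("\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; write artifacts under config.outdir.

    Without a GFF3 annotation the pipeline stops after signal analysis
    (annotation stages skipped and logged). Returns the summary dict.
    """
    config.validate()
    streams = [p for p in (config.reads, config.est_fasta) if p]
    if config.sam is None and not streams:
        raise ConfigurationError("either reads/est_fasta or sam is required")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = load_genome(config.genome_fasta)
    summary: dict = {"parameters": asdict(config), "counts": {}}

    # --- read processing --------------------------------------------------
    total_counts = rp.ProcessingCounts()
    oriented: list[rp.ReadRecord] = []
    calls: list[rp.TailCall] = []
    for stream in streams:
        recs, stream_calls, counts = rp.process_reads(
            rp.read_input(stream),
            min_run=config.min_run,
            q_threshold=config.q_threshold,
            min_fraction=config.min_fraction,
            min_mappable=config.min_mappable,
            adapter=config.adapter,
        )
        oriented.extend(recs)
        calls.extend(stream_calls)
        for key, val in counts.as_dict().items():
            setattr(total_counts, key, getattr(total_counts, key) + val)
        logger.info("processed %s: %s", stream, counts.as_dict())
    if streams:
        rp.write_oriented_fasta(oriented, outdir / "oriented.fa")
        rp.write_tail_table(oriented, calls, outdir / "tails.tsv")
    summary["counts"].update(total_counts.as_dict())
    summary["counts"]["raw_reads"] = total_counts.input
    summary["counts"]["tail_containing"] = total_counts.emitted

    # --- site calling -----------------------------------------------------
    if config.sam is not None:
        alignments = sc.import_sam(config.sam)
        summary["counts"].setdefault("raw_reads", len(alignments))
    else:
        alignments = sc.align_trimmed_reads(genome, oriented)
    summary["counts"]["uniquely_mapped"] = len(alignments)

    sites = sc.infer_cleavage_sites(alignments)
    summary["counts"]["cleavage_sites"] = len(sites)
    kept, artifacts = sc.filter_internal_priming(
        sites, genome, window=config.ip_window, min_run=config.ip_min_run
    )
    summary["counts"]["internal_priming_removed"] = len(artifacts)
    summary["counts"]["cleavage_sites_retained"] = len(kept)
    clusters = sc.cluster_sites(kept, max_gap=config.cluster_gap)
    summary["counts"]["pa_clusters"] = len(clusters)
    sc.write_clusters_bed(clusters, outdir / "clusters.bed")
    sc.write_members_tsv(clusters, outdir / "cluster_members.tsv")
    het = sc.heterogeneity_summary(clusters)
    summary["heterogeneity"] = het

    # --- signal analysis --------------------------------------------------
    if clusters:
        contexts = sig.extract_contexts(genome, clusters, config.flank)
        mono = sig.mononucleotide_profile(contexts)
        di = sig.dinucleotide_profile(contexts)
        sig.write_profile_tsv(mono, outdir / "mononucleotide_profile.tsv")
        sig.write_profile_tsv(di, outdir / "dinucleotide_profile.tsv")
        search_window = (-config.pas_window, -6)
        assignments = sig.assign_pas_all(
            contexts, search_window=search_window
        )
        sig.write_assignments_tsv(assignments, outdir / "pas_assignments.tsv")
        table = sig.pas_frequency_table(assignments)
        table.to_csv(outdir / "pas_frequency.tsv", sep="\t",
                     header=["percent"], index_label="motif")
        summary["pas_frequency_percent"] = {
            m: round(v, 4) for m, v in table.items()
        }
        dists = sig.hexamer_distributions(
            contexts,
            threshold=config.peak_threshold,
            min_total_fraction=config.peak_min_total_fraction,
        )
        sig.write_hexamer_tsv(dists, outdir / "hexamer_distributions.tsv")
        summary["signal_hexamers"] = sorted(
            d.hexamer for d in dists.values() if d.is_signal
        )
    else:
        logger.warning("no clusters called; signal analysis skipped")

    # --- APA annotation ---------------------------------------------------
    if config.gff3 is None:
        logger.warning("no GFF3 given; annotation stages skipped")
        summary["annotation"] = None
        write_summary(summary, outdir / "summary.json")
        return summary

    models = ann.load_annotation(config.gff3)
    index = ann.GeneIndex(models, extension=config.extension)
    assignments_g = [
        ann.assign_site_to_gene(c, index) for c in clusters
    ]
    with open(outdir / "site_gene_assignments.tsv", "w") as fh:
        fh.write("cluster_id\tgene_id\tfeature_class\tdistance_to_3end\n")
        for a in assignments_g:
            fh.write(
                f"{a.cluster_id}\t{a.gene_id or 'intergenic'}\t"
                f"{a.feature_class}\t"
                f"{'' if a.distance_to_three_end is None else a.distance_to_three_end}\n"
            )
    per_gene, hist, multi_frac = ann.apa_site_counts(assignments_g)
    chrom_table = ann.chromosome_distribution(
        clusters, models, assignments_g
    )
    chrom_table.to_csv(outdir / "chromosome_distribution.tsv", sep="\t")
    summary["annotation"] = {
        "n_genes": len(models),
        "genic_fraction": ann.genic_fraction(assignments_g),
        "feature_class_fractions": ann.feature_class_fractions(assignments_g),
        "apa_histogram": hist,
        "multi_site_gene_fraction": multi_frac,
    }
    write_summary(summary, outdir / "summary.json")
    return summary
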