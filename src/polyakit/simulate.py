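"""Synthetic genome / annotation / read generator with planted ground truth.

The generator emulates the statistical structure the pipeline assumes in real
poly(A)-selected data:

* a uniform-composition multi-chromosome genome,
* non-overlapping multi-exon gene models with UTRs on both strands,
* pA clusters planted at and downstream of annotated 3' ends, each carrying
  a PAS hexamer drawn from the published frequency table at a normally
  distributed offset upstream of the representative cleavage site, a CA
  cleavage dinucleotide at every member cleavage position, and a U/GU-rich
  (T/GT in DNA) downstream element,
* cleavage microheterogeneity (1, 2 or 3 member positions within 20 nt),
* reads carrying non-templated poly(A) tails (>= 10 nt), emitted in both
  orientations, with per-base substitution errors,
* internal-priming decoys: genomic A/T runs planted in introns and
  intergenic space from which tail-less reads with a false genomic "tail"
  are drawn,
* tail-less background reads, and a small fraction of uniformly low-quality
  reads to exercise the quality filter.

Everything is reproducible from ``SimConfig.seed``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotation import GeneModel, write_gff3
from .config import SimConfig
from .dna import revcomp
from .errors import CapacityError, ConfigurationError

logger = logging.getLogger(__name__)

# gene-architecture draws (nt); chosen to pack ~100 compact genes per 250 kb
# while keeping neighbouring genes' cluster windows (+200 nt past the 3'
# end) at least 200 nt apart so planted elements never collide
INTERGENIC_GAP = (600, 900)
EXON_LEN = (80, 200)
INTRON_LEN = (80, 300)
UTR5_LEN = (30, 60)
TERMINAL_CDS_LEN = (60, 150)
UTR3_LEN = (250, 400)
CHROM_EDGE_MARGIN = 1000

# pA-cluster placement relative to the annotated 3' end
CLUSTER_WINDOW_INSET = 40      # nt into the 3'UTR
CLUSTER_WINDOW_DOWNSTREAM = 200  # nt past the annotated 3' end (< 2 kb)
CLUSTER_MIN_SEPARATION = 80
MEMBER_MAX_OFFSET = 10         # members within +/-10 nt of the representative

GU_ELEMENT_SPAN = (5, 25)      # sense indices, inclusive
GU_BASE_PROBS = {"T": 0.55, "G": 0.30, "C": 0.10, "A": 0.05}
ARTIFACT_RUN_LEN = (10, 15)

HIGH_QUAL = "I"  # Q40
LOW_QUAL = "#"   # Q2


@dataclass(frozen=True)
class PlantedCluster:
    cluster_id: str
    gene_id: str
    chromosome: str
    strand: str
    representative: int          # between-base cleavage coordinate
    members: tuple[int, ...]     # includes the representative
    motif: str                   # DNA hexamer or "none"
    motif_offset: int | None     # sense-index of the motif start (-d)
    motif_genomic_start: int | None


@dataclass(frozen=True)
class ArtifactRun:
    run_id: str
    chromosome: str
    start: int
    length: int
    strand: str  # '+' = A-run (plus-sense decoy), '-' = T-run


@dataclass
class SimTruth:
    """Planted ground truth for recovery tests."""

    clusters: list[PlantedCluster] = field(default_factory=list)
    artifact_runs: list[ArtifactRun] = field(default_factory=list)
    #: per-read origin rows: read_id, kind (cluster|artifact|background),
    #: origin_id, chromosome, strand, true_site, low_quality
    read_origins: pd.DataFrame | None = None

    def clusters_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "cluster_id": c.cluster_id,
                    "gene_id": c.gene_id,
                    "chromosome": c.chromosome,
                    "strand": c.strand,
                    "representative": c.representative,
                    "members": ",".join(map(str, c.members)),
                    "motif": c.motif,
                    "motif_offset": (
                        "" if c.motif_offset is None else c.motif_offset
                    ),
                    "motif_genomic_start": (
                        "" if c.motif_genomic_start is None
                        else c.motif_genomic_start
                    ),
                }
                for c in self.clusters
            ]
        )

    def artifact_runs_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "run_id": r.run_id,
                    "chromosome": r.chromosome,
                    "start": r.start,
                    "length": r.length,
                    "strand": r.strand,
                }
                for r in self.artifact_runs
            ]
        )


Genome = dict[str, bytearray]


def _rng(config: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stage])


def genome_as_str(genome: Genome) -> dict[str, str]:
    return {name: seq.decode() for name, seq in genome.items()}


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def simulate_genome(config: SimConfig) -> tuple[Genome, pd.DataFrame]:
    """Uniform-composition genome; planted elements are added later."""
    config.validate()
    rng = _rng(config, 1)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    genome: Genome = {}
    rows = []
    for i in range(config.n_chromosomes):
        name = f"chr{i + 1}"
        seq = bases[rng.integers(0, 4, size=config.chrom_length)]
        genome[name] = bytearray(seq.tobytes())
        rows.append({"chromosome": name, "length": config.chrom_length})
    return genome, pd.DataFrame(rows)


def write_fasta(genome: Genome, path) -> None:
    records = [
        SeqRecord(Seq(seq.decode()), id=name, description="")
        for name, seq in genome.items()
    ]
    SeqIO.write(records, str(path), "fasta")  # 60-column wrap


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

def _draw_gene_segments(
    rng: np.random.Generator, n_exons: int
) -> list[tuple[str, int]]:
    """Sense-order (label, length) segments: utr5/cds/intron/utr3."""

    def u(lohi):
        return int(rng.integers(lohi[0], lohi[1] + 1))

    segments: list[tuple[str, int]] = []
    if n_exons == 1:
        segments += [
            ("utr5", u(UTR5_LEN)),
            ("cds", u(TERMINAL_CDS_LEN)),
            ("utr3", u(UTR3_LEN)),
        ]
        return segments
    segments += [("utr5", u(UTR5_LEN)), ("cds", u(TERMINAL_CDS_LEN))]
    for _ in range(n_exons - 2):
        segments += [("intron", u(INTRON_LEN)), ("cds", u(EXON_LEN))]
    segments += [
        ("intron", u(INTRON_LEN)),
        ("cds", u(TERMINAL_CDS_LEN)),
        ("utr3", u(UTR3_LEN)),
    ]
    return segments


def _segments_to_model(
    gene_id: str, chrom: str, strand: str, start: int,
    segments: Sequence[tuple[str, int]],
) -> GeneModel:
    """Lay sense-order segments onto the genome (reversed for minus strand)."""
    total = sum(length for _, length in segments)
    end = start + total
    genomic = segments if strand == "+" else list(reversed(segments))
    model = GeneModel(gene_id, chrom, strand, start, end)
    cursor = start
    exon_start: int | None = None
    for label, length in genomic:
        iv = (cursor, cursor + length)
        if label == "intron":
            if exon_start is not None:
                model.exons.append((exon_start, cursor))
                exon_start = None
        else:
            if exon_start is None:
                exon_start = cursor
            getattr(model, {"utr5": "utr5", "cds": "cds", "utr3": "utr3"}[label]).append(iv)
        cursor += length
    if exon_start is not None:
        model.exons.append((exon_start, cursor))
    return model


def simulate_gene_models(
    genome: Genome, config: SimConfig
) -> list[GeneModel]:
    """Place non-overlapping genes along the chromosomes, both strands."""
    config.validate()
    rng = _rng(config, 2)
    chrom_names = list(genome.keys())
    models: list[GeneModel] = []
    chrom_idx = 0
    cursor = CHROM_EDGE_MARGIN
    lo, hi = config.exons_per_gene
    for i in range(config.n_genes):
        strand = "+" if i % 2 == 0 else "-"
        segments = _draw_gene_segments(rng, int(rng.integers(lo, hi + 1)))
        total = sum(length for _, length in segments)
        while True:
            limit = len(genome[chrom_names[chrom_idx]]) - CHROM_EDGE_MARGIN
            if cursor + total <= limit:
                break
            chrom_idx += 1
            cursor = CHROM_EDGE_MARGIN
            if chrom_idx >= len(chrom_names):
                raise CapacityError(
                    f"genome too small: placed {i} of {config.n_genes} genes"
                )
        model = _segments_to_model(
            f"gene{i + 1:04d}", chrom_names[chrom_idx], strand, cursor,
            segments,
        )
        models.append(model)
        cursor = model.end + int(
            rng.integers(INTERGENIC_GAP[0], INTERGENIC_GAP[1] + 1)
        )
    return models


# ---------------------------------------------------------------------------
# planting
# ---------------------------------------------------------------------------

def _write_sense(
    genome: Genome, chrom: str, strand: str, pos: int, start_index: int,
    seq: str,
) -> tuple[int, int]:
    """Write `seq` at sense indices start_index.. relative to cleavage `pos`.

    Returns the genomic half-open interval written. Sense index i addresses
    genome[pos + i] on '+' and the complement of genome[pos - 1 - i] on '-'.
    """
    buf = genome[chrom]
    if strand == "+":
        g0 = pos + start_index
        buf[g0:g0 + len(seq)] = seq.encode()
        return g0, g0 + len(seq)
    g0 = pos - 1 - (start_index + len(seq) - 1)
    buf[g0:g0 + len(seq)] = revcomp(seq).encode()
    return g0, g0 + len(seq)


def _sample_separated(
    rng: np.random.Generator, lo: int, hi: int, k: int, min_sep: int
) -> list[int]:
    """k positions in [lo, hi] pairwise >= min_sep apart (even spacing as a
    fallback when rejection sampling fails)."""
    if hi - lo < (k - 1) * min_sep:
        raise CapacityError(
            f"window [{lo}, {hi}] too small for {k} sites at sep {min_sep}"
        )
    for _ in range(200):
        picks = sorted(int(rng.integers(lo, hi + 1)) for _ in range(k))
        if all(b - a >= min_sep for a, b in zip(picks, picks[1:])):
            return picks
    step = (hi - lo) // max(k - 1, 1) if k > 1 else 0
    return [lo + j * step for j in range(k)]


def _draw_categorical(rng: np.random.Generator, table: dict) -> object:
    keys = list(table.keys())
    probs = np.array([table[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    return keys[int(rng.choice(len(keys), p=probs))]


def _gu_element(rng: np.random.Generator, length: int) -> str:
    bases = list(GU_BASE_PROBS.keys())
    probs = np.array(list(GU_BASE_PROBS.values()))
    idx = rng.choice(len(bases), size=length, p=probs / probs.sum())
    return "".join(bases[i] for i in idx)


def _overlaps(occupied: set[int], interval: tuple[int, int]) -> bool:
    return any(b in occupied for b in range(*interval))


def plant_pa_sites(
    genome: Genome, models: Sequence[GeneModel], config: SimConfig
) -> SimTruth:
    """Plant pA clusters (motif + CA + downstream element) and decoy A-runs.

    Mutates `genome` in place and returns the planted truth.
    """
    config.validate()
    rng = _rng(config, 3)
    truth = SimTruth()
    occupied: dict[str, set[int]] = {name: set() for name in genome}
    cluster_serial = 0

    for model in models:
        k = int(_draw_categorical(rng, dict(config.sites_per_gene_dist)))
        if model.strand == "+":
            utr3_lo = min(s for s, _ in model.utr3)
            lo = utr3_lo + CLUSTER_WINDOW_INSET
            hi = model.end + CLUSTER_WINDOW_DOWNSTREAM
        else:
            utr3_hi = max(e for _, e in model.utr3)
            lo = model.start - CLUSTER_WINDOW_DOWNSTREAM
            hi = utr3_hi - CLUSTER_WINDOW_INSET
        reps = _sample_separated(rng, lo, hi, k, CLUSTER_MIN_SEPARATION)
        for rep in reps:
            cluster_serial += 1
            cid = f"pc{cluster_serial:05d}"
            truth.clusters.append(
                _plant_cluster(
                    genome, occupied, rng, config, cid, model, rep
                )
            )

    _plant_artifact_runs(genome, occupied, rng, config, models, truth)
    return truth


def _plant_cluster(
    genome: Genome, occupied: dict[str, set[int]],
    rng: np.random.Generator, config: SimConfig, cid: str,
    model: GeneModel, rep: int,
) -> PlantedCluster:
    chrom, strand = model.chrom, model.strand
    occ = occupied[chrom]

    # downstream U/GU-rich element (T/GT in DNA) at sense +5..+25
    if config.downstream_ug_enrichment:
        lo, hi = GU_ELEMENT_SPAN
        iv = _write_sense(
            genome, chrom, strand, rep, lo, _gu_element(rng, hi - lo + 1)
        )
        occ.update(range(*iv))

    # PAS motif (or none) upstream of the representative cleavage site
    motif = str(_draw_categorical(rng, dict(config.motif_frequency_table)))
    motif_offset: int | None = None
    motif_genomic: int | None = None
    if motif != "none":
        planted = False
        for _ in range(10):
            d = int(round(rng.normal(config.pas_offset_mean,
                                     config.pas_offset_sd)))
            d = min(max(d, 10), 30)
            if strand == "+":
                iv = (rep - d, rep - d + 6)
            else:
                iv = (rep + d - 6, rep + d)
            if not _overlaps(occ, iv):
                _write_sense(genome, chrom, strand, rep, -d, motif)
                occ.update(range(*iv))
                motif_offset, motif_genomic, planted = -d, iv[0], True
                break
        if not planted:
            logger.warning(
                "cluster %s: motif %s placement collided repeatedly; "
                "planting skipped", cid, motif,
            )
            motif = "none"

    # member cleavage positions within a 20-nt span, CA at each member.
    # Offsets live in sense space (positive = downstream); members stay
    # pairwise >= 2 nt apart so their CA dinucleotides never overlap, and
    # clear of the planted motif body.
    m = int(_draw_categorical(rng, dict(config.heterogeneity_dist)))
    forbidden: set[int] = set()
    if motif_offset is not None:
        forbidden = set(range(motif_offset - 1, motif_offset + 7))
    candidates = [
        o for o in range(-MEMBER_MAX_OFFSET, MEMBER_MAX_OFFSET + 1)
        if abs(o) >= 2 and o not in forbidden
    ]
    offsets = [0]
    for i in rng.permutation(len(candidates)):
        if len(offsets) == m:
            break
        o = candidates[int(i)]
        if all(abs(o - prev) >= 2 for prev in offsets):
            offsets.append(o)
    sign = 1 if strand == "+" else -1
    members = tuple(sorted(rep + sign * o for o in offsets))
    if config.downstream_ug_enrichment:
        for member in members:
            iv = _write_sense(genome, chrom, strand, member, -1, "CA")
            occ.update(range(*iv))

    return PlantedCluster(
        cluster_id=cid, gene_id=model.gene_id, chromosome=chrom,
        strand=strand, representative=rep, members=members, motif=motif,
        motif_offset=motif_offset, motif_genomic_start=motif_genomic,
    )


def _plant_artifact_runs(
    genome: Genome, occupied: dict[str, set[int]],
    rng: np.random.Generator, config: SimConfig,
    models: Sequence[GeneModel], truth: SimTruth,
) -> None:
    """Plant A/T runs in introns and intergenic space, clear of clusters."""
    if config.n_artifact_runs <= 0:
        return
    candidates: list[tuple[str, int, int]] = []
    for model in models:
        for s, e in model.introns:
            if e - s >= 60:
                candidates.append((model.chrom, s + 10, e - 10))
    # intergenic: complement of gene spans padded by the cluster window
    by_chrom: dict[str, list[tuple[int, int]]] = {n: [] for n in genome}
    for model in models:
        by_chrom[model.chrom].append(
            (model.start - CLUSTER_WINDOW_DOWNSTREAM - 100,
             model.end + CLUSTER_WINDOW_DOWNSTREAM + 100)
        )
    for name, spans in by_chrom.items():
        cursor = config.read_length + 10
        for s, e in sorted(spans):
            if s - cursor >= 60:
                candidates.append((name, cursor, s))
            cursor = max(cursor, e)
        tail_limit = len(genome[name]) - config.read_length - 10
        if tail_limit - cursor >= 60:
            candidates.append((name, cursor, tail_limit))
    if not candidates:
        raise CapacityError("no intron/intergenic space for artifact runs")
    weights = np.array([e - s for _, s, e in candidates], dtype=float)
    weights /= weights.sum()

    planted = 0
    attempts = 0
    while planted < config.n_artifact_runs and attempts < 20 * config.n_artifact_runs:
        attempts += 1
        chrom, s, e = candidates[int(rng.choice(len(candidates), p=weights))]
        length = int(rng.integers(ARTIFACT_RUN_LEN[0], ARTIFACT_RUN_LEN[1] + 1))
        if e - s <= length + 4:
            continue
        start = int(rng.integers(s + 2, e - length - 2))
        iv = (start - 1, start + length + 1)
        if _overlaps(occupied[chrom], iv):
            continue
        strand = "+" if planted % 2 == 0 else "-"
        base = b"A" if strand == "+" else b"T"
        other = b"C" if strand == "+" else b"G"
        buf = genome[chrom]
        buf[start:start + length] = base * length
        # pin the run boundaries so the run length is exactly `length`
        if buf[start - 1:start] == base:
            buf[start - 1:start] = other
        if buf[start + length:start + length + 1] == base:
            buf[start + length:start + length + 1] = other
        occupied[chrom].update(range(*iv))
        planted += 1
        truth.artifact_runs.append(
            ArtifactRun(f"ar{planted:04d}", chrom, start, length, strand)
        )
    if planted < config.n_artifact_runs:
        logger.warning(
            "planted only %d of %d artifact runs", planted,
            config.n_artifact_runs,
        )


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

def _apply_errors(
    rng: np.random.Generator, seq: str, error_rate: float
) -> str:
    if error_rate <= 0:
        return seq
    n_err = rng.binomial(len(seq), error_rate)
    if n_err == 0:
        return seq
    arr = bytearray(seq, "ascii")
    positions = rng.choice(len(seq), size=n_err, replace=False)
    for p in positions:
        alts = [b for b in b"ACGT" if b != arr[p]]
        arr[p] = alts[int(rng.integers(0, len(alts)))]
    return arr.decode()


def simulate_reads(
    genome: Genome, truth: SimTruth, config: SimConfig
) -> list[tuple[str, str, str]]:
    """Emit (read_id, sequence, quality) triples and fill truth.read_origins.

    Cluster reads are sense-strand fragments ending exactly at a member
    cleavage position plus a pure poly(A) tail; artifact reads end at the
    far end of a planted genomic A/T run (the run is their false tail);
    background reads carry no tail. Half of all reads are emitted
    reverse-complemented.
    """
    config.validate()
    rng = _rng(config, 4)
    gstr = genome_as_str(genome)
    n = config.n_reads
    n_art = int(round(n * config.internal_priming_rate)) if truth.artifact_runs else 0
    n_bg = int(round(n * config.background_read_rate))
    n_cluster = n - n_art - n_bg
    if n_cluster < 0:
        raise ConfigurationError(
            "internal_priming_rate + background_read_rate exceed 1"
        )

    reads: list[tuple[str, str, str]] = []
    origins: list[dict] = []
    serial = 0

    def emit(seq: str, kind: str, origin_id: str, chrom: str, strand: str,
             true_site: int) -> None:
        nonlocal serial
        serial += 1
        rid = f"r{serial:07d}"
        if rng.random() < 0.5:
            seq = revcomp(seq)
        seq = _apply_errors(rng, seq, config.error_rate)
        low = rng.random() < config.low_quality_rate
        qual = (LOW_QUAL if low else HIGH_QUAL) * len(seq)
        reads.append((rid, seq, qual))
        origins.append({
            "read_id": rid, "kind": kind, "origin_id": origin_id,
            "chromosome": chrom, "strand": strand, "true_site": true_site,
            "low_quality": low,
        })

    tlo, thi = config.tail_length_range
    clusters = truth.clusters
    if n_cluster > 0 and not clusters:
        raise ConfigurationError("no planted clusters to draw reads from")
    for ci in rng.integers(0, len(clusters), size=n_cluster) if n_cluster else []:
        c = clusters[int(ci)]
        m = len(c.members)
        if m == 1:
            member = c.representative
        else:
            weights = np.full(m, 0.4 / (m - 1))
            weights[c.members.index(c.representative)] = 0.6
            member = c.members[int(rng.choice(m, p=weights))]
        tail = int(rng.integers(tlo, thi + 1))
        frag_len = config.read_length - tail
        if c.strand == "+":
            frag = gstr[c.chromosome][member - frag_len:member]
        else:
            frag = revcomp(gstr[c.chromosome][member:member + frag_len])
        emit(frag + "A" * tail, "cluster", c.cluster_id, c.chromosome,
             c.strand, member)

    runs = truth.artifact_runs
    for ri in rng.integers(0, len(runs), size=n_art) if n_art else []:
        r = runs[int(ri)]
        if r.strand == "+":
            end = r.start + r.length
            seq = gstr[r.chromosome][end - config.read_length:end]
            site = r.start
        else:
            seq = revcomp(
                gstr[r.chromosome][r.start:r.start + config.read_length]
            )
            site = r.start + r.length
        emit(seq, "artifact", r.run_id, r.chromosome, r.strand, site)

    chrom_names = list(gstr.keys())
    for _ in range(n_bg):
        chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
        start = int(rng.integers(0, len(gstr[chrom]) - config.read_length))
        seq = gstr[chrom][start:start + config.read_length]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            seq = revcomp(seq)
        emit(seq, "background", "-", chrom, strand, -1)

    truth.read_origins = pd.DataFrame(origins)
    return reads


def write_fastq(reads: Sequence[tuple[str, str, str]], path) -> None:
    """Phred+33 FASTQ."""
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# direct context simulation (no genome / reads)
# ---------------------------------------------------------------------------

def simulate_contexts(
    config: SimConfig, n: int, motif_table: dict[str, float] | None = None,
):
    """Generate n cleavage-site contexts directly (no genome or reads).

    Each context is a random 200-nt window (sense indices -100..+99) with
    the downstream element and cleavage CA planted, plus a PAS motif drawn
    from `motif_table` (default: the config's table) at the configured
    offset. Returns (contexts, planted_classes) where planted classes are
    DNA hexamers or "none".
    """
    from .signal_analysis import SiteContext, DEFAULT_FLANK

    rng = _rng(config, 5)
    table = dict(motif_table or config.motif_frequency_table)
    flank = DEFAULT_FLANK
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    contexts: list[SiteContext] = []
    planted: list[str] = []
    for i in range(n):
        arr = bytearray(
            bases[rng.integers(0, 4, size=2 * flank)].tobytes()
        )
        if config.downstream_ug_enrichment:
            lo, hi = GU_ELEMENT_SPAN
            elem = _gu_element(rng, hi - lo + 1)
            arr[flank + lo:flank + hi + 1] = elem.encode()
            arr[flank - 1:flank + 1] = b"CA"
        motif = str(_draw_categorical(rng, table))
        if motif != "none":
            d = int(round(rng.normal(config.pas_offset_mean,
                                     config.pas_offset_sd)))
            d = min(max(d, 10), 30)
            arr[flank - d:flank - d + 6] = motif.encode()
        contexts.append(
            SiteContext(cluster_id=f"ctx{i + 1:05d}", seq_dna=arr.decode(),
                        flank=flank)
        )
        planted.append(motif)
    return contexts, planted


# ---------------------------------------------------------------------------
# one-call dataset emission
# ---------------------------------------------------------------------------

def simulate_dataset(config: SimConfig, outdir) -> dict[str, Path]:
    """Generate and write the full fixture; returns the emitted paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, chrom_table = simulate_genome(config)
    models = simulate_gene_models(genome, config)
    truth = plant_pa_sites(genome, models, config)
    reads = simulate_reads(genome, truth, config)

    paths = {
        "genome": outdir / "genome.fa",
        "annotation": outdir / "annotation.gff3",
        "reads": outdir / "reads.fastq",
        "chromosomes": outdir / "chromosomes.tsv",
        "truth_clusters": outdir / "truth_clusters.tsv",
        "truth_artifact_runs": outdir / "truth_artifact_runs.tsv",
        "truth_read_origins": outdir / "truth_read_origins.tsv",
        "config": outdir / "config.yaml",
    }
    write_fasta(genome, paths["genome"])
    write_gff3(models, paths["annotation"])
    write_fastq(reads, paths["reads"])
    chrom_table.to_csv(paths["chromosomes"], sep="\t", index=False)
    truth.clusters_frame().to_csv(
        paths["truth_clusters"], sep="\t", index=False
    )
    truth.artifact_runs_frame().to_csv(
        paths["truth_artifact_runs"], sep="\t", index=False
    )
    truth.read_origins.to_csv(
        paths["truth_read_origins"], sep="\t", index=False
    )
    config.to_yaml(paths["config"])
    return paths
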