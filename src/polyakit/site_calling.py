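"""Cleavage-site inference, internal-priming filtering and pA clustering.

Oriented trimmed reads are located on the genome (built-in exact-match
search for small synthetic genomes, or an external SAM for real data),
their 3' ends define between-base cleavage coordinates, sites whose
downstream genomic window contains a run of >= 8 consecutive A (sense
strand) are removed as internal-priming artifacts, and the survivors are
merged into pA clusters by single-linkage chaining at <= 20 bp.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pysam

from .dna import max_run, revcomp
from .errors import FormatError
from .read_processing import ReadRecord

DEFAULT_IP_WINDOW = 20
DEFAULT_IP_MIN_RUN = 8
DEFAULT_CLUSTER_GAP = 20


@dataclass(frozen=True)
class Alignment:
    read_id: str
    chromosome: str
    start: int   # 0-based reference start
    end: int     # exclusive reference end
    strand: str  # '+': oriented read matches forward genome


@dataclass(frozen=True)
class CleavageSite:
    chromosome: str
    position: int  # between-base, 0-based
    strand: str
    support: int


@dataclass
class PACluster:
    """A group of cleavage sites chained at <= max_gap between neighbours."""

    cluster_id: str
    chromosome: str
    strand: str
    members: list[CleavageSite] = field(default_factory=list)

    @property
    def representative_position(self) -> int:
        """Member with highest support; ties resolve to smallest position."""
        best = max(self.members, key=lambda s: (s.support, -s.position))
        return best.position

    @property
    def span(self) -> tuple[int, int]:
        positions = [s.position for s in self.members]
        return min(positions), max(positions)

    @property
    def total_support(self) -> int:
        return sum(s.support for s in self.members)

    @property
    def n_members(self) -> int:
        return len(self.members)


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

SEED_K = 20


class GenomeIndex:
    """Seed table of all k-mers of a small genome for exact-match search.

    A full-length occurrence of a read implies its leading k-mer occurs at
    the same position, so seed candidates cover every occurrence and
    uniqueness can be decided exactly.
    """

    def __init__(self, genome: dict[str, str], k: int = SEED_K):
        self.genome = genome
        self.k = k
        self._seeds: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for chrom, ref in genome.items():
            for i in range(len(ref) - k + 1):
                self._seeds[ref[i:i + k]].append((chrom, i))
        self._seeds.default_factory = None  # freeze

    def occurrences(self, seq: str, limit: int = 2) -> list[tuple[str, int]]:
        """All genomic positions where `seq` occurs verbatim (up to limit)."""
        if len(seq) < self.k:
            # rare short reads: fall back to a direct scan
            out = []
            for chrom, ref in self.genome.items():
                pos = ref.find(seq)
                while pos >= 0 and len(out) < limit:
                    out.append((chrom, pos))
                    pos = ref.find(seq, pos + 1)
            return out
        out = []
        for chrom, pos in self._seeds.get(seq[:self.k], ()):
            ref = self.genome[chrom]
            if ref[pos:pos + len(seq)] == seq:
                out.append((chrom, pos))
                if len(out) >= limit:
                    break
        return out


def align_trimmed_reads(
    genome: dict[str, str] | GenomeIndex, reads: Iterable[ReadRecord]
) -> list[Alignment]:
    """Exact-match seeded search over both strands; only unique hits kept.

    Intended for small synthetic genomes (<= ~10 Mb); real data should
    enter through import_sam. A read matching the forward strand is a
    sense-oriented plus-strand transcript end; a read whose reverse
    complement matches is a minus-strand transcript end. Reads with
    mismatches (or occurring at two or more loci) are dropped.
    """
    index = genome if isinstance(genome, GenomeIndex) else GenomeIndex(genome)
    alignments: list[Alignment] = []
    for read in reads:
        seq = read.sequence
        fwd = index.occurrences(seq)
        rev = index.occurrences(revcomp(seq)) if len(fwd) < 2 else []
        if len(fwd) + len(rev) != 1:
            continue
        if fwd:
            chrom, pos = fwd[0]
            strand = "+"
        else:
            chrom, pos = rev[0]
            strand = "-"
        alignments.append(
            Alignment(read.read_id, chrom, pos, pos + len(seq), strand)
        )
    return alignments


def import_sam(sam_path) -> list[Alignment]:
    """Alignments of oriented trimmed reads from a SAM file.

    Drops unmapped, secondary, supplementary and MAPQ-0 records; the
    reference end honours CIGAR reference-consuming operations.
    """
    try:
        fh = pysam.AlignmentFile(str(sam_path), "r")
    except ValueError as exc:
        raise FormatError(f"cannot open SAM {sam_path}: {exc}") from exc
    with fh:
        if not fh.header.get("SQ"):
            raise FormatError(f"SAM {sam_path} lacks @SQ header lines")
        out: list[Alignment] = []
        for rec in fh:
            if (
                rec.is_unmapped
                or rec.is_secondary
                or rec.is_supplementary
                or rec.mapping_quality == 0
            ):
                continue
            out.append(
                Alignment(
                    rec.query_name,
                    rec.reference_name,
                    rec.reference_start,
                    rec.reference_end,
                    "-" if rec.is_reverse else "+",
                )
            )
    return out


# ---------------------------------------------------------------------------
# cleavage sites
# ---------------------------------------------------------------------------

def infer_cleavage_sites(
    alignments: Iterable[Alignment],
) -> list[CleavageSite]:
    """3' ends of oriented alignments as between-base cleavage coordinates.

    Plus-strand alignments cleave at the reference end, minus-strand ones
    at the reference start; identical sites aggregate read support.
    """
    counts: Counter[tuple[str, str, int]] = Counter()
    for aln in alignments:
        pos = aln.end if aln.strand == "+" else aln.start
        counts[(aln.chromosome, aln.strand, pos)] += 1
    sites = [
        CleavageSite(chrom, pos, strand, support)
        for (chrom, strand, pos), support in counts.items()
    ]
    sites.sort(key=lambda s: (s.chromosome, s.strand, s.position))
    return sites


def downstream_window(
    site: CleavageSite, genome: dict[str, str],
    window: int = DEFAULT_IP_WINDOW,
) -> str:
    """Sense-strand genomic sequence immediately downstream of the site.

    Truncated at chromosome ends. For minus-strand sites this is the
    reverse complement of the window upstream in genome coordinates.
    """
    ref = genome[site.chromosome]
    if site.strand == "+":
        return ref[site.position:site.position + window]
    return revcomp(ref[max(0, site.position - window):site.position])


def is_internal_priming(
    site: CleavageSite, genome: dict[str, str],
    window: int = DEFAULT_IP_WINDOW,
    min_run: int = DEFAULT_IP_MIN_RUN,
) -> bool:
    """Artifact iff the downstream window contains >= min_run consecutive A."""
    return max_run(downstream_window(site, genome, window), "A") >= min_run


def filter_internal_priming(
    sites: Sequence[CleavageSite], genome: dict[str, str],
    window: int = DEFAULT_IP_WINDOW,
    min_run: int = DEFAULT_IP_MIN_RUN,
) -> tuple[list[CleavageSite], list[CleavageSite]]:
    """Split sites into (retained, artifacts)."""
    kept: list[CleavageSite] = []
    removed: list[CleavageSite] = []
    for site in sites:
        (removed if is_internal_priming(site, genome, window, min_run)
         else kept).append(site)
    return kept, removed


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def cluster_sites(
    sites: Iterable[CleavageSite],
    max_gap: int = DEFAULT_CLUSTER_GAP,
) -> list[PACluster]:
    """Single-linkage chaining of same-chromosome, same-strand sites.

    Consecutive sites <= max_gap apart join one cluster; a chain may span
    more than max_gap overall. The partition is order-invariant (input is
    sorted internally) and conserves total support.
    """
    by_group: dict[tuple[str, str], list[CleavageSite]] = defaultdict(list)
    for site in sites:
        by_group[(site.chromosome, site.strand)].append(site)
    clusters: list[PACluster] = []
    for (chrom, strand) in sorted(by_group):
        group = sorted(by_group[(chrom, strand)], key=lambda s: s.position)
        current: list[CleavageSite] = []
        for site in group:
            if current and site.position - current[-1].position > max_gap:
                clusters.append(
                    PACluster("", chrom, strand, current)
                )
                current = []
            current.append(site)
        if current:
            clusters.append(PACluster("", chrom, strand, current))
    clusters.sort(
        key=lambda c: (c.chromosome, c.span[0], c.strand)
    )
    for i, c in enumerate(clusters):
        c.cluster_id = f"PA{i + 1:05d}"
    return clusters


def heterogeneity_summary(
    clusters: Sequence[PACluster],
) -> dict[str, object]:
    """Counts and fractions of clusters with 1, 2 or >2 cleavage sites.

    Fractions are None for an empty cluster list (not silently 0/0).
    """
    n1 = sum(1 for c in clusters if c.n_members == 1)
    n2 = sum(1 for c in clusters if c.n_members == 2)
    n_more = sum(1 for c in clusters if c.n_members > 2)
    total = len(clusters)
    fractions = (
        None if total == 0
        else {"1": n1 / total, "2": n2 / total, ">2": n_more / total}
    )
    return {
        "counts": {"1": n1, "2": n2, ">2": n_more},
        "total": total,
        "fractions": fractions,
    }


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------

def write_clusters_bed(clusters: Sequence[PACluster], path) -> None:
    """BED6: chrom, span-start, span-end (exclusive), id, total_support, strand."""
    with open(path, "w") as fh:
        for c in clusters:
            lo, hi = c.span
            fh.write(
                f"{c.chromosome}\t{lo}\t{hi + 1}\t{c.cluster_id}\t"
                f"{c.total_support}\t{c.strand}\n"
            )


def write_members_tsv(clusters: Sequence[PACluster], path) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\tchromosome\tstrand\tposition\tsupport\n")
        for c in clusters:
            for s in sorted(c.members, key=lambda s: s.position):
                fh.write(
                    f"{c.cluster_id}\t{c.chromosome}\t{c.strand}\t"
                    f"{s.position}\t{s.support}\n"
                )
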