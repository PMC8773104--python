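"""Gene models, site-to-gene assignment and APA summaries.

A pA cluster is assigned to a gene when its representative cleavage position
falls inside the gene span or inside a strand-aware 2 kb 3' extension; the
extension compensates for incomplete 3'UTR annotation. Feature classification
uses the last transcribed base of the cluster (the base immediately upstream
of the between-base cleavage coordinate in transcript direction) with
precedence 3'UTR > 5'UTR > exon(CDS) > intron when annotated intervals
overlap. Positions in the extension are classified as extended-3' and
reported under 3'UTR.
"""

from __future__ import annotations

import tempfile
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
from intervaltree import IntervalTree

from .errors import ClassificationError, FormatError

DEFAULT_EXTENSION = 2000

Interval = tuple[int, int]  # half-open, 0-based


@dataclass
class GeneModel:
    """Union-over-transcripts structure of one gene.

    All intervals are half-open 0-based. Introns are the gaps between
    consecutive exons of the exon union.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[Interval] = field(default_factory=list)
    cds: list[Interval] = field(default_factory=list)
    utr5: list[Interval] = field(default_factory=list)
    utr3: list[Interval] = field(default_factory=list)

    @property
    def introns(self) -> list[Interval]:
        merged = merge_intervals(self.exons)
        return [
            (merged[i][1], merged[i + 1][0]) for i in range(len(merged) - 1)
        ]

    @property
    def three_prime_end(self) -> int:
        """Between-base coordinate of the annotated transcript 3' terminus."""
        return self.end if self.strand == "+" else self.start

    def extension_interval(self, extension: int = DEFAULT_EXTENSION) -> Interval:
        """Genomic interval of the 3' extension (may be clipped at 0)."""
        if self.strand == "+":
            return (self.end, self.end + extension)
        return (max(0, self.start - extension), self.start)

    def assignment_interval(self, extension: int = DEFAULT_EXTENSION) -> Interval:
        """Gene span plus the 3' extension, as one genomic interval."""
        if self.strand == "+":
            return (self.start, self.end + extension)
        return (max(0, self.start - extension), self.end)


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Sorted union of half-open intervals (adjacent intervals merge)."""
    out: list[list[int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


# ---------------------------------------------------------------------------
# GFF3 I/O
# ---------------------------------------------------------------------------

def write_gff3(models: Sequence[GeneModel], path) -> None:
    """Emit gene/mRNA/exon/CDS/UTR features, 1-based inclusive per GFF3."""

    def line(chrom, ftype, s, e, strand, attrs):
        return (
            f"{chrom}\tpolyakit\t{ftype}\t{s + 1}\t{e}\t.\t{strand}\t.\t{attrs}"
        )

    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(models, key=lambda m: (m.chrom, m.start, m.gene_id)):
            mrna_id = f"{g.gene_id}.t1"
            fh.write(
                line(g.chrom, "gene", g.start, g.end, g.strand,
                     f"ID={g.gene_id}") + "\n"
            )
            fh.write(
                line(g.chrom, "mRNA", g.start, g.end, g.strand,
                     f"ID={mrna_id};Parent={g.gene_id}") + "\n"
            )
            for ftype, ivs in (
                ("exon", g.exons),
                ("CDS", g.cds),
                ("five_prime_UTR", g.utr5),
                ("three_prime_UTR", g.utr3),
            ):
                for s, e in sorted(ivs):
                    fh.write(
                        line(g.chrom, ftype, s, e, g.strand,
                             f"Parent={mrna_id}") + "\n"
                    )


def load_annotation(gff3_path) -> list[GeneModel]:
    """Parse a GFF3 into GeneModels (features unioned over transcripts)."""
    try:
        db = gffutils.create_db(
            str(gff3_path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # pragma: no cover - gffutils message wrapped
        raise FormatError(f"cannot parse GFF3 {gff3_path}: {exc}") from exc

    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        model = GeneModel(
            gene_id=gene.id,
            chrom=gene.seqid,
            strand=gene.strand,
            start=gene.start - 1,
            end=gene.end,
        )
        buckets = {
            "exon": [], "CDS": [],
            "five_prime_UTR": [], "three_prime_UTR": [],
        }
        for child in db.children(gene.id):
            if child.featuretype in buckets:
                if child.start < 1 or child.end < child.start:
                    raise FormatError(f"out-of-bounds feature: {child}")
                buckets[child.featuretype].append((child.start - 1, child.end))
        model.exons = merge_intervals(buckets["exon"])
        model.cds = merge_intervals(buckets["CDS"])
        model.utr5 = merge_intervals(buckets["five_prime_UTR"])
        model.utr3 = merge_intervals(buckets["three_prime_UTR"])
        models.append(model)
    models.sort(key=lambda m: (m.chrom, m.start, m.gene_id))
    return models


# ---------------------------------------------------------------------------
# Site-to-gene assignment
# ---------------------------------------------------------------------------

FEATURE_3UTR = "3'UTR"
FEATURE_EXT3 = "extended-3'"
FEATURE_5UTR = "5'UTR"
FEATURE_EXON = "exon(CDS)"
FEATURE_INTRON = "intron"
INTERGENIC = "intergenic"

#: reporting order of genic feature classes (extended-3' folds into 3'UTR)
GENIC_CLASSES = (FEATURE_3UTR, FEATURE_5UTR, FEATURE_EXON, FEATURE_INTRON)


@dataclass(frozen=True)
class SiteGeneAssignment:
    cluster_id: str
    gene_id: str | None
    feature_class: str
    distance_to_three_end: int | None


class GeneIndex:
    """Interval index over gene spans + 3' extensions, per (chrom, strand)."""

    def __init__(self, models: Sequence[GeneModel],
                 extension: int = DEFAULT_EXTENSION):
        self.extension = extension
        self.models = {m.gene_id: m for m in models}
        self._trees: dict[tuple[str, str], IntervalTree] = defaultdict(
            IntervalTree
        )
        for m in models:
            s, e = m.assignment_interval(extension)
            if e > s:
                self._trees[(m.chrom, m.strand)].addi(s, e, m.gene_id)

    def candidates(self, chrom: str, strand: str, base: int) -> list[GeneModel]:
        tree = self._trees.get((chrom, strand))
        if tree is None:
            return []
        return [self.models[iv.data] for iv in tree.at(base)]


def site_base(position: int, strand: str) -> int:
    """Last transcribed base for a between-base cleavage coordinate."""
    return position - 1 if strand == "+" else position


def assign_site_to_gene(cluster, index: GeneIndex) -> SiteGeneAssignment:
    """Assign one cluster to a gene (or intergenic) and classify its feature.

    Among overlapping candidate genes the one whose annotated 3' end is
    nearest to the cluster's representative position wins.
    """
    base = site_base(cluster.representative_position, cluster.strand)
    cands = index.candidates(cluster.chromosome, cluster.strand, base)
    if not cands:
        return SiteGeneAssignment(cluster.cluster_id, None, INTERGENIC, None)
    gene = min(
        cands,
        key=lambda g: (
            abs(cluster.representative_position - g.three_prime_end),
            g.gene_id,
        ),
    )
    feature = classify_feature(cluster, gene, index.extension)
    dist = abs(cluster.representative_position - gene.three_prime_end)
    return SiteGeneAssignment(cluster.cluster_id, gene.gene_id, feature, dist)


def classify_feature(cluster, gene: GeneModel,
                     extension: int = DEFAULT_EXTENSION) -> str:
    """Feature class of a cluster assigned to `gene`.

    Precedence where annotation intervals overlap or abut:
    3'UTR > 5'UTR > exon(CDS) > intron; extension positions -> extended-3'.
    """
    base = site_base(cluster.representative_position, cluster.strand)

    def contains(ivs: Iterable[Interval]) -> bool:
        return any(s <= base < e for s, e in ivs)

    if contains(gene.utr3):
        return FEATURE_3UTR
    if contains(gene.utr5):
        return FEATURE_5UTR
    if contains(gene.cds):
        return FEATURE_EXON
    if contains(gene.exons):
        # exonic but outside CDS/UTR annotation: count with exon(CDS)
        return FEATURE_EXON
    if contains(gene.introns):
        return FEATURE_INTRON
    s, e = gene.extension_interval(extension)
    if s <= base < e:
        return FEATURE_EXT3
    raise ClassificationError(
        f"cluster {cluster.cluster_id} at {cluster.chromosome}:"
        f"{cluster.representative_position}({cluster.strand}) lies in no "
        f"feature of gene {gene.gene_id}"
    )


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

APA_BINS = ("1", "2", "3", "4", "5", ">5")


def apa_site_counts(
    assignments: Sequence[SiteGeneAssignment],
) -> tuple[dict[str, int], dict[str, int], float | None]:
    """Per-gene cluster counts, the {1,2,3,4,5,>5} histogram, and the
    fraction of genes carrying >= 2 sites (None when no gene has a site)."""
    per_gene: Counter[str] = Counter(
        a.gene_id for a in assignments if a.gene_id is not None
    )
    hist = {b: 0 for b in APA_BINS}
    for n in per_gene.values():
        hist[str(n) if n <= 5 else ">5"] += 1
    if not per_gene:
        return {}, hist, None
    multi = sum(1 for n in per_gene.values() if n >= 2)
    return dict(per_gene), hist, multi / len(per_gene)


def feature_class_fractions(
    assignments: Sequence[SiteGeneAssignment],
) -> dict[str, float]:
    """Fractions of genic clusters per feature class (extended-3' -> 3'UTR)."""
    genic = [a for a in assignments if a.gene_id is not None]
    counts = Counter(
        FEATURE_3UTR if a.feature_class == FEATURE_EXT3 else a.feature_class
        for a in genic
    )
    n = len(genic)
    return {c: (counts.get(c, 0) / n if n else 0.0) for c in GENIC_CLASSES}


def chromosome_distribution(
    clusters, models: Sequence[GeneModel],
    assignments: Sequence[SiteGeneAssignment],
) -> pd.DataFrame:
    """Per-chromosome gene / cluster / genic / intergenic counts."""
    genic_ids = {a.cluster_id for a in assignments if a.gene_id is not None}
    rows: dict[str, dict[str, int]] = {}
    for m in models:
        row = rows.setdefault(
            m.chrom,
            {"genes": 0, "clusters": 0, "genic": 0, "intergenic": 0},
        )
        row["genes"] += 1
    for c in clusters:
        row = rows.setdefault(
            c.chromosome,
            {"genes": 0, "clusters": 0, "genic": 0, "intergenic": 0},
        )
        row["clusters"] += 1
        if c.cluster_id in genic_ids:
            row["genic"] += 1
        else:
            row["intergenic"] += 1
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    df.index.name = "chromosome"
    return df


def genic_fraction(assignments: Sequence[SiteGeneAssignment]) -> float | None:
    if not assignments:
        return None
    return sum(1 for a in assignments if a.gene_id is not None) / len(
        assignments
    )
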