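"""Simulation configuration and the default PAS motif frequency table.

The default planting frequencies are the published usage frequencies of the
14 canonical-and-variant polyadenylation-signal hexamers in the pig
transcriptome (plus a "none" class for sites with no recognizable signal).
The printed percentages sum to 100.02 due to rounding; the planting table
normalizes them to probabilities summing to exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import yaml

from .errors import ConfigurationError

# (DNA hexamer, published frequency in %) in the canonical reporting order;
# "none" = no recognizable PAS hexamer in the upstream search window.
PAS_MOTIF_PERCENTS: tuple[tuple[str, float], ...] = (
    ("AATAAA", 50.96),
    ("ATTAAA", 12.39),
    ("TATAAA", 4.45),
    ("AGTAAA", 3.93),
    ("AAGAAA", 2.63),
    ("AATATA", 2.25),
    ("AATACA", 2.23),
    ("CATAAA", 2.25),
    ("GATAAA", 2.09),
    ("AATGAA", 0.59),
    ("TTTAAA", 1.15),
    ("ACTAAA", 1.36),
    ("AATAGA", 1.21),
    ("AAAAAG", 1.89),
    ("none", 10.64),
)

#: Assignment hierarchy (DNA alphabet), canonical AAUAAA first, then the
#: variants in descending published frequency order.
PAS_HIERARCHY_DNA: tuple[str, ...] = tuple(
    m for m, _ in PAS_MOTIF_PERCENTS if m != "none"
)


def default_motif_table() -> dict[str, float]:
    """Published motif percentages normalized to probabilities (sum == 1)."""
    total = sum(p for _, p in PAS_MOTIF_PERCENTS)
    return {m: p / total for m, p in PAS_MOTIF_PERCENTS}


@dataclass
class SimConfig:
    """Parameters of the synthetic genome / annotation / read generator.

    Defaults describe the standard study fixture: a 2 x 250 kb genome
    carrying 200 genes, ~600 planted pA clusters (uniform 1..5 clusters per
    gene) and 100,000 reads at error rate 0.002 with 5% internally primed
    reads.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 250_000
    n_genes: int = 200
    exons_per_gene: tuple[int, int] = (2, 4)
    #: hexamer (DNA) -> planting probability, plus a "none" probability.
    motif_frequency_table: Mapping[str, float] = field(
        default_factory=default_motif_table
    )
    #: PAS body starts pas_offset nt upstream of the cleavage site.
    pas_offset_mean: float = 16.0
    pas_offset_sd: float = 3.0
    #: number of distinct cleavage positions per cluster -> probability.
    heterogeneity_dist: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.3376, 2: 0.1941, 3: 0.4683}
    )
    #: number of pA clusters per gene -> probability (APA structure).
    sites_per_gene_dist: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.2, 2: 0.2, 3: 0.2, 4: 0.2, 5: 0.2}
    )
    tail_length_range: tuple[int, int] = (12, 35)
    read_length: int = 80
    n_reads: int = 100_000
    error_rate: float = 0.002
    #: fraction of reads generated from genomic A-run (internal priming) decoys.
    internal_priming_rate: float = 0.05
    #: fraction of tail-less background reads drawn uniformly from the genome.
    background_read_rate: float = 0.05
    #: number of A/T-run decoys planted in introns and intergenic space.
    n_artifact_runs: int = 60
    #: fraction of reads emitted with uniformly low base qualities, to give
    #: the quality filter something to remove.
    low_quality_rate: float = 0.01
    downstream_ug_enrichment: bool = True

    def validate(self) -> None:
        counts = {
            "n_chromosomes": self.n_chromosomes,
            "chrom_length": self.chrom_length,
            "n_genes": self.n_genes,
            "read_length": self.read_length,
            "n_reads": self.n_reads,
        }
        for name, value in counts.items():
            if int(value) <= 0:
                raise ConfigurationError(f"{name} must be > 0 (got {value})")
        lo, hi = self.exons_per_gene
        if lo < 1 or hi < lo:
            raise ConfigurationError(
                f"exons_per_gene must be a range with 1 <= lo <= hi "
                f"(got {self.exons_per_gene})"
            )
        total = sum(self.motif_frequency_table.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"motif_frequency_table probabilities must sum to 1 "
                f"(got {total!r})"
            )
        for motif in self.motif_frequency_table:
            if motif != "none" and (
                len(motif) != 6 or set(motif) - set("ACGT")
            ):
                raise ConfigurationError(
                    f"motif_frequency_table key {motif!r} is not a DNA hexamer"
                )
        if not 10 <= self.pas_offset_mean <= 30:
            raise ConfigurationError(
                f"pas_offset_mean must lie in [10, 30] nt upstream "
                f"(got {self.pas_offset_mean})"
            )
        if self.pas_offset_sd < 0:
            raise ConfigurationError("pas_offset_sd must be >= 0")
        for dname, dist in (
            ("heterogeneity_dist", self.heterogeneity_dist),
            ("sites_per_gene_dist", self.sites_per_gene_dist),
        ):
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ConfigurationError(f"{dname} must sum to 1")
            if any(k < 1 for k in dist):
                raise ConfigurationError(f"{dname} supports counts >= 1 only")
        tlo, thi = self.tail_length_range
        if tlo < 10 or thi < tlo:
            raise ConfigurationError(
                f"tail_length_range minimum must be >= 10 "
                f"(got {self.tail_length_range})"
            )
        if thi >= self.read_length - 20:
            raise ConfigurationError(
                "tail_length_range max leaves < 20 nt of mappable sequence"
            )
        for rname, rate in (
            ("error_rate", self.error_rate),
            ("internal_priming_rate", self.internal_priming_rate),
            ("background_read_rate", self.background_read_rate),
            ("low_quality_rate", self.low_quality_rate),
        ):
            if not 0.0 <= rate <= 1.0:
                raise ConfigurationError(f"{rname} must be in [0, 1]")
        if self.internal_priming_rate > 0 and self.n_artifact_runs <= 0:
            raise ConfigurationError(
                "n_artifact_runs must be > 0 when internal_priming_rate > 0"
            )

    # -- serialization -----------------------------------------------------
    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["exons_per_gene"] = list(self.exons_per_gene)
        data["tail_length_range"] = list(self.tail_length_range)
        data["motif_frequency_table"] = dict(self.motif_frequency_table)
        data["heterogeneity_dist"] = {
            int(k): float(v) for k, v in self.heterogeneity_dist.items()
        }
        data["sites_per_gene_dist"] = {
            int(k): float(v) for k, v in self.sites_per_gene_dist.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        for key in ("exons_per_gene", "tail_length_range"):
            if key in data:
                data[key] = tuple(data[key])
        cfg = cls(**data)
        cfg.validate()
        return cfg
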