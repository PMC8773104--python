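"""Shared fixtures: the default study fixture processed through every
pipeline stage once per session, plus a small fast dataset."""

from __future__ import annotations

from types import SimpleNamespace

import pytest

from polyakit import SimConfig
from polyakit.read_processing import ReadRecord, process_reads
from polyakit.signal_analysis import extract_contexts
from polyakit.simulate import (
    genome_as_str,
    plant_pa_sites,
    simulate_gene_models,
    simulate_genome,
    simulate_reads,
)
from polyakit.site_calling import (
    align_trimmed_reads,
    cluster_sites,
    filter_internal_priming,
    infer_cleavage_sites,
)

FULL_SEED = 1


def run_stages(cfg: SimConfig) -> SimpleNamespace:
    """Generate a dataset and run all library stages on it."""
    genome, _ = simulate_genome(cfg)
    models = simulate_gene_models(genome, cfg)
    truth = plant_pa_sites(genome, models, cfg)
    raw = simulate_reads(genome, truth, cfg)
    oriented, calls, counts = process_reads(
        [ReadRecord(*r) for r in raw]
    )
    gstr = genome_as_str(genome)
    alignments = align_trimmed_reads(gstr, oriented)
    sites = infer_cleavage_sites(alignments)
    kept, removed = filter_internal_priming(sites, gstr)
    clusters = cluster_sites(kept)
    contexts = extract_contexts(gstr, clusters) if clusters else []
    return SimpleNamespace(
        config=cfg, genome=gstr, models=models, truth=truth, raw=raw,
        oriented=oriented, tail_calls=calls, counts=counts,
        alignments=alignments, sites=sites, kept=kept, removed=removed,
        clusters=clusters, contexts=contexts,
    )


@pytest.fixture(scope="session")
def full_run() -> SimpleNamespace:
    """Default study conditions: 2 x 250 kb, 200 genes, ~600 clusters,
    100,000 reads, error rate 0.002, 5% internally primed reads."""
    return run_stages(SimConfig(seed=FULL_SEED))


@pytest.fixture(scope="session")
def small_clean_run() -> SimpleNamespace:
    """Small noise-free dataset (no errors, no artifacts, no background)."""
    cfg = SimConfig(
        seed=11, n_genes=20, n_reads=3000, chrom_length=80_000,
        error_rate=0.0, internal_priming_rate=0.0,
        background_read_rate=0.0, low_quality_rate=0.0,
    )
    return run_stages(cfg)


@pytest.fixture(scope="session")
def small_dataset_dir(tmp_path_factory):
    """Small on-disk fixture (FASTA/GFF3/FASTQ/truth TSVs)."""
    from polyakit.simulate import simulate_dataset

    cfg = SimConfig(seed=5, n_genes=20, n_reads=5000, chrom_length=80_000)
    outdir = tmp_path_factory.mktemp("fixture")
    paths = simulate_dataset(cfg, outdir)
    return SimpleNamespace(config=cfg, paths=paths, outdir=outdir)
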