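"""Site calling: alignment, cleavage inference, internal-priming filter,
clustering and heterogeneity."""

from __future__ import annotations

import re
from itertools import groupby

import numpy as np
import pytest

from polyakit.dna import revcomp
from polyakit.errors import FormatError
from polyakit.read_processing import ReadRecord
from polyakit.site_calling import (
    Alignment,
    CleavageSite,
    align_trimmed_reads,
    cluster_sites,
    filter_internal_priming,
    heterogeneity_summary,
    import_sam,
    infer_cleavage_sites,
    is_internal_priming,
)


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

def test_exact_forward_and_reverse_alignment():
    rng = np.random.default_rng(0)
    ref = "".join(rng.choice(list("ACGT"), size=5000))
    genome = {"c1": ref}
    fwd = ReadRecord("f", ref[1000:1040], None)
    rev = ReadRecord("r", revcomp(ref[2000:2030]), None)
    out = {a.read_id: a for a in align_trimmed_reads(genome, [fwd, rev])}
    assert out["f"] == Alignment("f", "c1", 1000, 1040, "+")
    assert out["r"] == Alignment("r", "c1", 2000, 2030, "-")


def test_multi_locus_and_mismatched_reads_dropped():
    ref = "ACGTACCGGT" * 10 + "TTTTGGGGCCCCAAA" + "ACGTACCGGT" * 10
    genome = {"c1": ref}
    repeat = ReadRecord("rep", "ACGTACCGGT" * 3, None)
    novel = ReadRecord("nov", "ACGTAGGGTTCAGGCCATGCATCG", None)
    assert align_trimmed_reads(genome, [repeat, novel]) == []


def test_noise_free_synthetic_reads_align_uniquely(small_clean_run):
    run = small_clean_run
    assert len(run.alignments) == len(run.oriented)
    origins = run.truth.read_origins.set_index("read_id")
    for a in run.alignments[:200]:
        row = origins.loc[a.read_id]
        assert a.chromosome == row["chromosome"]
        assert a.strand == row["strand"]
        end = a.end if a.strand == "+" else a.start
        assert end == row["true_site"]


# ---------------------------------------------------------------------------
# SAM import
# ---------------------------------------------------------------------------

SAM_TEXT = """@HD\tVN:1.6\tSO:unknown
@SQ\tSN:chr1\tLN:1000
ok\t0\tchr1\t101\t60\t30M\t*\t0\t0\t{seq30}\t*
cigar\t16\tchr1\t201\t60\t10M5D20M\t*\t0\t0\t{seq30}\t*
unmapped\t4\t*\t0\t0\t*\t*\t0\t0\t{seq30}\t*
secondary\t256\tchr1\t301\t60\t30M\t*\t0\t0\t{seq30}\t*
mapq0\t0\tchr1\t401\t0\t30M\t*\t0\t0\t{seq30}\t*
""".format(seq30="A" * 30)


def test_import_sam_filters_and_cigar_end(tmp_path):
    path = tmp_path / "in.sam"
    path.write_text(SAM_TEXT)
    out = {a.read_id: a for a in import_sam(path)}
    assert set(out) == {"ok", "cigar"}
    assert out["ok"] == Alignment("ok", "chr1", 100, 130, "+")
    # 10M5D20M consumes 35 reference bases; flag 16 -> minus strand
    assert out["cigar"] == Alignment("cigar", "chr1", 200, 235, "-")


def test_import_sam_requires_header(tmp_path):
    path = tmp_path / "bad.sam"
    path.write_text("r1\t0\tchr1\t10\t60\t5M\t*\t0\t0\tACGTA\t*\n")
    with pytest.raises(FormatError):
        import_sam(path)


# ---------------------------------------------------------------------------
# cleavage inference
# ---------------------------------------------------------------------------

def test_cleavage_positions_and_aggregation():
    alns = [
        Alignment("a", "c1", 1000, 1040, "+"),
        Alignment("b", "c1", 1010, 1040, "+"),
        Alignment("c", "c1", 2000, 2030, "-"),
    ]
    sites = infer_cleavage_sites(alns)
    assert sites == [
        CleavageSite("c1", 1040, "+", 2),
        CleavageSite("c1", 2000, "-", 1),
    ]


# ---------------------------------------------------------------------------
# internal-priming filter
# ---------------------------------------------------------------------------

def _site_with_downstream(window: str, strand: str = "+") -> tuple:
    if strand == "+":
        genome = {"c": "G" * 50 + window + "G" * 10}
        return CleavageSite("c", 50, "+", 1), genome
    genome = {"c": "G" * 10 + revcomp(window) + "G" * 50}
    return CleavageSite("c", 10 + len(window), "-", 1), genome


@pytest.mark.parametrize("strand", ["+", "-"])
@pytest.mark.parametrize(
    "window, artifact",
    [
        ("AAAAAAAA" + "TCGATCGATCGA", True),   # exactly 8 As
        ("AAAAAAA" + "TCGATCGATCGAT", False),  # 7 As
        ("TCGA" + "A" * 9 + "TCGATCG", True),  # interior run
        ("ATATATATATATATATATAT", False),
    ],
)
def test_internal_priming_decision(window, artifact, strand):
    site, genome = _site_with_downstream(window, strand)
    assert is_internal_priming(site, genome) is artifact


def test_truncated_window_at_chromosome_end():
    genome = {"c": "G" * 20 + "A" * 8}
    site = CleavageSite("c", 20, "+", 1)
    assert is_internal_priming(site, genome)
    short = CleavageSite("c", 24, "+", 1)  # only 4 As remain in view
    assert not is_internal_priming(short, genome)


def test_filter_oracle_equivalence_random_windows():
    rng = np.random.default_rng(42)
    for _ in range(2000):
        window = "".join(
            rng.choice(list("ACGT"), size=20, p=[0.5, 0.17, 0.17, 0.16])
        )
        site, genome = _site_with_downstream(window)
        expected = any(
            len(m) >= 8 for m in re.findall(r"A+", window)
        )
        assert is_internal_priming(site, genome) is expected


def test_no_retained_site_has_downstream_a_run(full_run):
    assert all(
        not is_internal_priming(s, full_run.genome) for s in full_run.kept
    )


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def sites_at(positions, strand="+", chrom="c1", support=1):
    return [CleavageSite(chrom, p, strand, support) for p in positions]


def test_chaining_splits_on_gap():
    clusters = cluster_sites(sites_at([100, 115, 140]))
    assert [sorted(s.position for s in c.members) for c in clusters] == [
        [100, 115], [140]
    ]


def test_strands_never_merge():
    clusters = cluster_sites(
        sites_at([100]) + sites_at([100], strand="-")
    )
    assert len(clusters) == 2
    assert {c.strand for c in clusters} == {"+", "-"}


def test_singleton_cluster_identity():
    (c,) = cluster_sites(sites_at([500], support=3))
    assert c.n_members == 1
    assert c.representative_position == 500
    assert c.total_support == 3


def test_representative_support_and_tie_break():
    sites = [
        CleavageSite("c1", 100, "+", 2),
        CleavageSite("c1", 105, "+", 5),
        CleavageSite("c1", 110, "+", 5),
    ]
    (c,) = cluster_sites(sites)
    assert c.representative_position == 105  # tie -> smallest position


def _partition_oracle(positions, max_gap=20):
    """Union-find over all pairs within max_gap (exhaustive)."""
    parent = list(range(len(positions)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(positions)):
        for j in range(i + 1, len(positions)):
            if abs(positions[i] - positions[j]) <= max_gap:
                parent[find(i)] = find(j)
    groups = {}
    for i, p in enumerate(positions):
        groups.setdefault(find(i), set()).add(p)
    return {frozenset(g) for g in groups.values()}


def test_clustering_matches_exhaustive_oracle():
    rng = np.random.default_rng(7)
    for _ in range(300):
        n = int(rng.integers(1, 30))
        positions = sorted(set(rng.integers(0, 400, size=n).tolist()))
        clusters = cluster_sites(sites_at(positions))
        got = {
            frozenset(s.position for s in c.members) for c in clusters
        }
        assert got == _partition_oracle(positions)


def test_clustering_order_invariant_and_conserves_support():
    rng = np.random.default_rng(13)
    positions = rng.integers(0, 2000, size=60).tolist()
    sites = [
        CleavageSite("c1", int(p), "+", int(rng.integers(1, 5)))
        for p in set(positions)
    ]
    ref = cluster_sites(sites)
    shuffled = list(sites)
    rng.shuffle(shuffled)
    again = cluster_sites(shuffled)
    as_sets = lambda cs: {
        frozenset((s.position, s.support) for s in c.members) for c in cs
    }
    assert as_sets(ref) == as_sets(again)
    assert sum(c.total_support for c in ref) == sum(s.support for s in sites)
    # consecutive-member gaps within clusters never exceed the threshold
    for c in ref:
        pos = sorted(s.position for s in c.members)
        assert all(b - a <= 20 for a, b in zip(pos, pos[1:]))


# ---------------------------------------------------------------------------
# heterogeneity
# ---------------------------------------------------------------------------

def test_heterogeneity_fractions_arithmetic():
    clusters = []
    for members in ([100], [300], [500, 505], [700, 705, 710]):
        clusters.extend(cluster_sites(sites_at(members)))
    summary = heterogeneity_summary(clusters)
    assert summary["fractions"] == {"1": 0.5, "2": 0.25, ">2": 0.25}
    assert summary["counts"] == {"1": 2, "2": 1, ">2": 1}


def test_heterogeneity_empty_input_reports_undefined():
    summary = heterogeneity_summary([])
    assert summary["fractions"] is None
    assert summary["counts"] == {"1": 0, "2": 0, ">2": 0}


def test_all_singleton_planting_recovers_all_singletons():
    from polyakit import SimConfig
    from conftest import run_stages

    cfg = SimConfig(
        seed=21, n_genes=12, n_reads=2500, chrom_length=60_000,
        error_rate=0.0, internal_priming_rate=0.0,
        background_read_rate=0.0, low_quality_rate=0.0,
        heterogeneity_dist={1: 1.0},
    )
    run = run_stages(cfg)
    summary = heterogeneity_summary(run.clusters)
    assert summary["fractions"]["1"] == 1.0
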