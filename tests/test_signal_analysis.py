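"""Signal analysis: context extraction, positional profiles, hexamer scan
and PAS motif assignment."""

from __future__ import annotations

import numpy as np
import pytest

from polyakit.dna import revcomp
from polyakit.errors import ConfigurationError, PolyakitError
from polyakit.signal_analysis import (
    DEFAULT_HIERARCHY,
    SiteContext,
    assign_pas,
    assign_pas_all,
    dinucleotide_profile,
    extract_context,
    hexamer_positional_counts,
    hexamer_start_positions,
    mononucleotide_profile,
    pas_frequency_table,
    peak_score,
)
from polyakit.site_calling import CleavageSite, PACluster


def cluster_at(pos, strand="+", chrom="c1"):
    return PACluster("x", chrom, strand, [CleavageSite(chrom, pos, strand, 1)])


def ctx_from(seq_dna: str, cid="x") -> SiteContext:
    assert len(seq_dna) == 200
    return SiteContext(cid, seq_dna)


def place(background: str, inserts: dict[int, str]) -> str:
    """Write DNA snippets at signed context indices into a 200-nt window."""
    arr = bytearray(background * 200, "ascii")[:200]
    for idx, snippet in inserts.items():
        arr[idx + 100:idx + 100 + len(snippet)] = snippet.encode()
    return arr.decode()


# ---------------------------------------------------------------------------
# context extraction
# ---------------------------------------------------------------------------

def test_context_indexing_contract():
    rng = np.random.default_rng(1)
    ref = "".join(rng.choice(list("ACGT"), size=1000))
    pos = 400
    ctx = extract_context({"c1": ref}, cluster_at(pos))
    assert ctx.base_at(0) == ref[pos].replace("T", "U")
    assert ctx.base_at(-1) == ref[pos - 1].replace("T", "U")
    assert ctx.base_at(-100) == ref[pos - 100].replace("T", "U")
    assert ctx.base_at(99) == ref[pos + 99].replace("T", "U")
    assert len(ctx.seq_dna) == 200


def test_reverse_complement_symmetry():
    rng = np.random.default_rng(2)
    ref = "".join(rng.choice(list("ACGT"), size=600))
    pos = 300
    plus = extract_context({"a": ref}, cluster_at(pos, "+", "a"))
    minus = extract_context(
        {"b": revcomp(ref)}, cluster_at(len(ref) - pos, "-", "b")
    )
    assert plus.seq_dna == minus.seq_dna


def test_edge_truncation_is_padded():
    ref = "ACGT" * 50
    ctx = extract_context({"c1": ref}, cluster_at(30))
    assert len(ctx.seq_dna) == 200
    assert ctx.seq_dna[:70] == "N" * 70
    assert ctx.padded


def test_planted_motif_visible_in_context(full_run):
    """Closed loop with truth: AATAAA planted at offset -16 reads AAUAAA at
    context indices -16..-11 of the recovered representative's context."""
    by_key = {
        (c.chromosome, c.strand, c.representative_position): c
        for c in full_run.clusters
    }
    checked = 0
    for t in full_run.truth.clusters:
        if t.motif != "AATAAA" or t.motif_offset != -16:
            continue
        rec = by_key.get((t.chromosome, t.strand, t.representative))
        if rec is None:
            continue
        ctx = extract_context(full_run.genome, rec)
        assert ctx.seq_rna[100 - 16:100 - 10] == "AAUAAA"
        checked += 1
        if checked >= 25:
            break
    assert checked >= 10


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------

def test_mononucleotide_profile_basics():
    contexts = [ctx_from(place("A", {})), ctx_from(place("G", {}))]
    prof = mononucleotide_profile(contexts)
    a_idx = prof.symbols.index("A")
    assert prof.frequencies[a_idx, 0] == 0.5
    assert np.allclose(prof.frequencies.sum(axis=0), 1.0)
    with pytest.raises(PolyakitError):
        mononucleotide_profile([])


def test_padding_excluded_from_denominators():
    padded = ctx_from("N" * 50 + "A" * 150)
    full = ctx_from("C" * 200)
    prof = mononucleotide_profile([padded, full])
    assert prof.denominators[0] == 1
    assert prof.frequencies[prof.symbols.index("C"), 0] == 1.0
    assert np.allclose(prof.frequencies.sum(axis=0), 1.0)


def test_dinucleotide_ca_counted_at_minus_one():
    seq = place("G", {-1: "CA"})
    prof = dinucleotide_profile([ctx_from(seq)])
    ca = prof.symbols.index("CA")
    pos_of = {p: i for i, p in enumerate(prof.positions)}
    assert prof.frequencies[ca, pos_of[-1]] == 1.0
    assert prof.frequencies[ca, pos_of[0]] == 0.0
    assert np.allclose(prof.frequencies.sum(axis=0), 1.0)


def test_uniform_contexts_have_uniform_dinucleotides():
    rng = np.random.default_rng(3)
    contexts = [
        ctx_from("".join(rng.choice(list("ACGT"), size=200)))
        for _ in range(400)
    ]
    prof = dinucleotide_profile(contexts)
    # 3 SD band around 1/16 for a binomial with n=400
    sd = np.sqrt((1 / 16) * (15 / 16) / 400)
    assert np.quantile(np.abs(prof.frequencies - 1 / 16), 0.995) < 4 * sd


def test_planted_downstream_element_elevates_uu(full_run):
    prof = dinucleotide_profile(full_run.contexts)
    uu = prof.symbols.index("UU")
    pos = prof.positions
    elem = prof.frequencies[uu, (pos >= 5) & (pos <= 24)].mean()
    background = prof.frequencies[uu, (pos >= -100) & (pos <= -50)].mean()
    assert elem > 2 * background


def test_cleavage_dinucleotide_recovered(full_run):
    """Planted CA at -1..0 dominates the recovered profiles."""
    mono = mononucleotide_profile(full_run.contexts)
    pos_of = {p: i for i, p in enumerate(mono.positions)}
    a_at_0 = mono.frequencies[mono.symbols.index("A"), pos_of[0]]
    assert a_at_0 > 0.9


# ---------------------------------------------------------------------------
# hexamer scan
# ---------------------------------------------------------------------------

def test_overlapping_hexamer_occurrences_each_count():
    seq = "A" * 7 + "CGTCG" * 38 + "CGT"
    counts = hexamer_positional_counts([ctx_from(seq[:200])])
    aaaaaa = counts["AAAAAA"]
    positions = hexamer_start_positions()
    assert aaaaaa[positions == -100] == 1
    assert aaaaaa[positions == -99] == 1
    assert aaaaaa.sum() == 2


def test_counts_complete_per_position():
    rng = np.random.default_rng(4)
    contexts = [
        ctx_from("".join(rng.choice(list("ACGT"), size=200)))
        for _ in range(20)
    ]
    counts = hexamer_positional_counts(contexts)
    total = sum(arr for arr in counts.values())
    assert (total == len(contexts)).all()


def test_hexamer_counts_match_substring_oracle():
    rng = np.random.default_rng(5)
    contexts = [
        ctx_from("".join(
            rng.choice(list("ACGT"), size=200, p=[0.4, 0.2, 0.2, 0.2])
        ))
        for _ in range(100)
    ]
    counts = hexamer_positional_counts(contexts)
    oracle: dict[tuple[str, int], int] = {}
    for ctx in contexts:
        seq = ctx.seq_rna
        for p in range(195):
            oracle[(seq[p:p + 6], p)] = oracle.get((seq[p:p + 6], p), 0) + 1
    for (hexamer, p), n in oracle.items():
        assert counts[hexamer][p] == n
    assert sum(a.sum() for a in counts.values()) == sum(oracle.values())


def test_peak_score_arithmetic_and_null():
    positions = hexamer_start_positions()
    counts = np.zeros(positions.size, dtype=np.int64)
    in_signal = (positions >= -30) & (positions <= -11)
    counts[in_signal] = 5  # 100 occurrences over the 20 signal positions
    score, is_sig = peak_score(counts, n_contexts=200)
    assert score == pytest.approx((100 / 20) / 0.5)  # background floored
    assert is_sig
    flat = np.ones(positions.size, dtype=np.int64)
    score_flat, is_sig_flat = peak_score(flat, n_contexts=200)
    assert score_flat == pytest.approx(1.0, abs=0.05)
    assert not is_sig_flat


def test_peak_score_rejects_overlapping_windows():
    counts = np.zeros(195, dtype=np.int64)
    with pytest.raises(ConfigurationError):
        peak_score(counts, 10, signal_window=(-30, 25),
                   background_window=(20, 94))


# ---------------------------------------------------------------------------
# PAS assignment
# ---------------------------------------------------------------------------

def test_hierarchy_precedence():
    seq = place("G", {-30: "ATTAAA", -16: "AATAAA"})
    a = assign_pas(ctx_from(seq))
    assert (a.motif, a.position, a.rank) == ("AAUAAA", -16, 1)


def test_most_three_prime_occurrence_wins():
    seq = place("G", {-35: "AATAAA", -16: "AATAAA"})
    a = assign_pas(ctx_from(seq))
    assert a.position == -16
    # substring oracle sees both occurrences
    rna = ctx_from(seq).seq_rna
    assert rna.count("AAUAAA") == 2


def test_out_of_window_motif_yields_none():
    seq = place("G", {-60: "AATAAA"})
    a = assign_pas(ctx_from(seq))
    assert a.motif is None and a.position is None and a.rank is None


def test_window_boundaries_inclusive():
    at_40 = assign_pas(ctx_from(place("G", {-40: "AATAAA"})))
    assert at_40.position == -40
    at_6 = assign_pas(ctx_from(place("G", {-6: "AATAAA"})))
    assert at_6.position == -6
    at_5 = assign_pas(ctx_from(place("G", {-5: "AATAAA"})))
    assert at_5.motif is None
    at_41 = assign_pas(ctx_from(place("G", {-41: "AATAAA"})))
    assert at_41.motif is None


def test_assignment_consistent_with_hexamer_counts(full_run):
    contexts = full_run.contexts[:200]
    counts = hexamer_positional_counts(contexts)
    positions = hexamer_start_positions()
    for ctx in contexts:
        a = assign_pas(ctx)
        if a.motif is None:
            continue
        assert counts[a.motif][positions == a.position] >= 1
        assert ctx.seq_rna[a.position + 100:a.position + 106] == a.motif


def test_hierarchy_monotonicity(full_run):
    """Dropping a motif only demotes its own clusters, never others."""
    contexts = full_run.contexts
    before = assign_pas_all(contexts)
    reduced = tuple(m for m in DEFAULT_HIERARCHY if m != "AAUAAA")
    after = assign_pas_all(contexts, hierarchy=reduced)
    rank_of = {m: i for i, m in enumerate(DEFAULT_HIERARCHY)}
    for b, a in zip(before, after):
        if b.motif == "AAUAAA":
            assert a.motif is None or rank_of[a.motif] > rank_of["AAUAAA"]
        else:
            assert (a.motif, a.position) == (b.motif, b.position)


def test_pas_frequency_table_arithmetic():
    contexts = [
        ctx_from(place("G", {-16: "AATAAA"}), "c1"),
        ctx_from(place("G", {-20: "AATAAA"}), "c2"),
        ctx_from(place("G", {-16: "ATTAAA"}), "c3"),
        ctx_from(place("G", {}), "c4"),
    ]
    table = pas_frequency_table(assign_pas_all(contexts))
    assert table["AAUAAA"] == 50.0
    assert table["AUUAAA"] == 25.0
    assert table["none"] == 25.0
    assert table.sum() == pytest.approx(100.0, abs=0.1)


def test_all_none_planting_gives_all_none():
    contexts = [ctx_from(place("G", {}), f"c{i}") for i in range(5)]
    table = pas_frequency_table(assign_pas_all(contexts))
    assert table["none"] == 100.0
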