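"""Positional nucleotide/hexamer analysis around cleavage sites and PAS
motif assignment.

Contexts are 200-nt sense-strand windows, indices -100..+99 with the
cleavage site at 0 (index 0 holds the first base downstream of cleavage;
index -1 the last transcribed base). Reporting uses the RNA alphabet
(T -> U); windows truncated at chromosome ends are padded with N and the
padding is excluded from every denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .config import PAS_HIERARCHY_DNA
from .dna import dna_to_rna, revcomp
from .errors import ConfigurationError, PolyakitError
from .site_calling import PACluster

DEFAULT_FLANK = 100
PAD = "N"

MONO_SYMBOLS = ("A", "C", "G", "U")
DI_SYMBOLS = tuple(a + b for a in MONO_SYMBOLS for b in MONO_SYMBOLS)

#: hexamer assignment hierarchy in the RNA alphabet, canonical AAUAAA first
DEFAULT_HIERARCHY: tuple[str, ...] = tuple(
    dna_to_rna(m) for m in PAS_HIERARCHY_DNA
)

DEFAULT_SEARCH_WINDOW = (-40, -6)     # hexamer start positions, inclusive
DEFAULT_SIGNAL_WINDOW = (-30, -11)    # start positions of a -25..-10 body
DEFAULT_BACKGROUND_WINDOW = (20, 94)
DEFAULT_PEAK_THRESHOLD = 3.0
DEFAULT_MIN_TOTAL_FRACTION = 0.005
PEAK_PSEUDOCOUNT = 0.5


@dataclass(frozen=True)
class SiteContext:
    """Sense-strand window around one cluster's representative site."""

    cluster_id: str
    seq_dna: str          # length 2*flank, N-padded at chromosome edges
    flank: int = DEFAULT_FLANK

    @property
    def seq_rna(self) -> str:
        return dna_to_rna(self.seq_dna)

    def base_at(self, index: int) -> str:
        """RNA base at a signed context index (-flank .. flank-1)."""
        return self.seq_rna[index + self.flank]

    @property
    def padded(self) -> bool:
        return PAD in self.seq_dna


@dataclass
class PositionalProfile:
    symbols: tuple[str, ...]
    positions: np.ndarray      # signed context indices
    frequencies: np.ndarray    # len(symbols) x len(positions)
    denominators: np.ndarray   # non-padded contexts per position

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.frequencies.T, index=self.positions, columns=self.symbols
        )
        df.index.name = "position"
        return df


@dataclass
class HexamerDistribution:
    hexamer: str               # RNA alphabet
    positions: np.ndarray      # start indices
    counts: np.ndarray
    total: int
    peak_score: float = 0.0
    is_signal: bool = False

    @property
    def peak_position(self) -> int:
        """Mode of the positional distribution (smallest index on ties)."""
        return int(self.positions[int(np.argmax(self.counts))])


@dataclass(frozen=True)
class PASAssignment:
    cluster_id: str
    motif: Optional[str]       # RNA hexamer, or None
    position: Optional[int]    # start index of the assigned occurrence
    rank: Optional[int]        # 1-based rank in the hierarchy


# ---------------------------------------------------------------------------
# context extraction
# ---------------------------------------------------------------------------

def extract_context(
    genome: Mapping[str, str], cluster: PACluster,
    flank: int = DEFAULT_FLANK,
) -> SiteContext:
    """Window around the representative site, sense-strand oriented.

    Plus strand: genome[pos-flank : pos+flank]; minus strand: the reverse
    complement of the same genomic slice. Chromosome-edge truncation is
    N-padded so index arithmetic stays valid.
    """
    pos = cluster.representative_position
    ref = genome[cluster.chromosome]
    if not 0 <= pos <= len(ref):
        raise PolyakitError(
            f"cluster {cluster.cluster_id} position {pos} outside "
            f"{cluster.chromosome}"
        )
    lo, hi = pos - flank, pos + flank
    left_pad = max(0, -lo)
    right_pad = max(0, hi - len(ref))
    window = PAD * left_pad + ref[max(0, lo):min(hi, len(ref))] + PAD * right_pad
    if cluster.strand == "-":
        window = revcomp(window)
    return SiteContext(cluster.cluster_id, window, flank)


def extract_contexts(
    genome: Mapping[str, str], clusters: Iterable[PACluster],
    flank: int = DEFAULT_FLANK,
) -> list[SiteContext]:
    return [extract_context(genome, c, flank) for c in clusters]


# ---------------------------------------------------------------------------
# positional profiles
# ---------------------------------------------------------------------------

def _context_matrix(contexts: Sequence[SiteContext]) -> np.ndarray:
    if not contexts:
        raise PolyakitError("profile requires at least one context")
    width = 2 * contexts[0].flank
    mat = np.frombuffer(
        "".join(c.seq_rna for c in contexts).encode(), dtype="S1"
    ).reshape(len(contexts), width)
    return mat


def mononucleotide_profile(
    contexts: Sequence[SiteContext],
) -> PositionalProfile:
    """Per-position A/C/G/U frequencies; padding excluded from denominators."""
    mat = _context_matrix(contexts)
    flank = contexts[0].flank
    valid = mat != PAD.encode()
    denom = valid.sum(axis=0).astype(float)
    freqs = np.zeros((len(MONO_SYMBOLS), mat.shape[1]))
    with np.errstate(invalid="ignore", divide="ignore"):
        for i, sym in enumerate(MONO_SYMBOLS):
            freqs[i] = (mat == sym.encode()).sum(axis=0) / denom
    return PositionalProfile(
        MONO_SYMBOLS, np.arange(-flank, flank), freqs, denom
    )


def dinucleotide_profile(
    contexts: Sequence[SiteContext],
) -> PositionalProfile:
    """Dinucleotide at position i = symbols at (i, i+1); 16 symbols."""
    mat = _context_matrix(contexts)
    flank = contexts[0].flank
    first, second = mat[:, :-1], mat[:, 1:]
    valid = (first != PAD.encode()) & (second != PAD.encode())
    denom = valid.sum(axis=0).astype(float)
    freqs = np.zeros((len(DI_SYMBOLS), first.shape[1]))
    with np.errstate(invalid="ignore", divide="ignore"):
        for i, sym in enumerate(DI_SYMBOLS):
            hit = (first == sym[0].encode()) & (second == sym[1].encode())
            freqs[i] = hit.sum(axis=0) / denom
    return PositionalProfile(
        DI_SYMBOLS, np.arange(-flank, flank - 1), freqs, denom
    )


# ---------------------------------------------------------------------------
# hexamer scan
# ---------------------------------------------------------------------------

def hexamer_positional_counts(
    contexts: Sequence[SiteContext],
) -> dict[str, np.ndarray]:
    """Count, per hexamer, the contexts containing it at each start index.

    Returns a map RNA-hexamer -> counts over start positions
    -flank .. flank-6 (every occurrence counts once at its own start).
    Hexamers overlapping padding are skipped.
    """
    if not contexts:
        raise PolyakitError("hexamer scan requires at least one context")
    flank = contexts[0].flank
    width = 2 * flank - 5
    counts: dict[str, np.ndarray] = {}
    for ctx in contexts:
        seq = ctx.seq_rna
        for p in range(width):
            hexamer = seq[p:p + 6]
            if PAD in hexamer:
                continue
            arr = counts.get(hexamer)
            if arr is None:
                arr = np.zeros(width, dtype=np.int64)
                counts[hexamer] = arr
            arr[p] += 1
    return counts


def hexamer_start_positions(flank: int = DEFAULT_FLANK) -> np.ndarray:
    return np.arange(-flank, flank - 5)


def peak_score(
    counts: np.ndarray,
    n_contexts: int,
    flank: int = DEFAULT_FLANK,
    signal_window: tuple[int, int] = DEFAULT_SIGNAL_WINDOW,
    background_window: tuple[int, int] = DEFAULT_BACKGROUND_WINDOW,
    threshold: float = DEFAULT_PEAK_THRESHOLD,
    min_total_fraction: float = DEFAULT_MIN_TOTAL_FRACTION,
) -> tuple[float, bool]:
    """Peak-vs-scatter statistic for one hexamer's positional counts.

    score = mean count/position in the signal window divided by the mean
    count/position in the background window (floored at a 0.5 pseudo-count);
    a hexamer is a signal when score >= threshold and its total occurrence
    count reaches min_total_fraction of the contexts.
    """
    s_lo, s_hi = signal_window
    b_lo, b_hi = background_window
    if s_hi >= b_lo and b_hi >= s_lo:
        raise ConfigurationError(
            f"signal window {signal_window} overlaps background window "
            f"{background_window}"
        )
    positions = hexamer_start_positions(flank)
    sig = counts[(positions >= s_lo) & (positions <= s_hi)]
    bg = counts[(positions >= b_lo) & (positions <= b_hi)]
    if sig.size == 0 or bg.size == 0:
        raise ConfigurationError(
            "peak-score windows fall outside the context"
        )
    mean_sig = float(sig.mean())
    mean_bg = max(float(bg.mean()), PEAK_PSEUDOCOUNT)
    score = mean_sig / mean_bg
    total = int(counts.sum())
    is_signal = (
        score >= threshold and total >= min_total_fraction * n_contexts
    )
    return score, is_signal


def hexamer_distributions(
    contexts: Sequence[SiteContext],
    hexamers: Optional[Iterable[str]] = None,
    **peak_kwargs,
) -> dict[str, HexamerDistribution]:
    """HexamerDistributions (with peak scores) for all observed hexamers,
    or a requested subset (unobserved requested hexamers get zero counts)."""
    counts = hexamer_positional_counts(contexts)
    flank = contexts[0].flank
    positions = hexamer_start_positions(flank)
    names = sorted(counts) if hexamers is None else list(hexamers)
    out: dict[str, HexamerDistribution] = {}
    for name in names:
        arr = counts.get(name, np.zeros(positions.size, dtype=np.int64))
        score, is_sig = peak_score(
            arr, len(contexts), flank=flank, **peak_kwargs
        )
        out[name] = HexamerDistribution(
            name, positions, arr, int(arr.sum()), score, is_sig
        )
    return out


# ---------------------------------------------------------------------------
# PAS assignment
# ---------------------------------------------------------------------------

def assign_pas(
    context: SiteContext,
    hierarchy: Sequence[str] = DEFAULT_HIERARCHY,
    search_window: tuple[int, int] = DEFAULT_SEARCH_WINDOW,
) -> PASAssignment:
    """First hierarchy motif with an occurrence in the upstream window wins;
    among its occurrences the most 3' (closest to cleavage) is recorded."""
    seq = context.seq_rna
    flank = context.flank
    w_lo, w_hi = search_window
    lo = max(w_lo + flank, 0)
    hi = min(w_hi + flank, len(seq) - 6)
    for rank, motif in enumerate(hierarchy, start=1):
        best: Optional[int] = None
        start = seq.find(motif, lo, hi + 6)
        while start >= 0 and start <= hi:
            best = start
            start = seq.find(motif, start + 1, hi + 6)
        if best is not None:
            return PASAssignment(
                context.cluster_id, motif, best - flank, rank
            )
    return PASAssignment(context.cluster_id, None, None, None)


def assign_pas_all(
    contexts: Sequence[SiteContext],
    hierarchy: Sequence[str] = DEFAULT_HIERARCHY,
    search_window: tuple[int, int] = DEFAULT_SEARCH_WINDOW,
) -> list[PASAssignment]:
    return [assign_pas(c, hierarchy, search_window) for c in contexts]


def pas_frequency_table(
    assignments: Sequence[PASAssignment],
    hierarchy: Sequence[str] = DEFAULT_HIERARCHY,
) -> pd.Series:
    """Motif -> percentage over all clusters, in hierarchy order + 'none'."""
    if not assignments:
        raise PolyakitError("frequency table requires >= 1 assignment")
    n = len(assignments)
    counts = {m: 0 for m in hierarchy}
    counts["none"] = 0
    for a in assignments:
        counts[a.motif if a.motif is not None else "none"] += 1
    return pd.Series(
        {m: 100.0 * c / n for m, c in counts.items()}, name="percent"
    )


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------

def write_profile_tsv(profile: PositionalProfile, path) -> None:
    profile.to_frame().to_csv(path, sep="\t", float_format="%.6f")


def write_assignments_tsv(
    assignments: Sequence[PASAssignment], path
) -> None:
    from .dna import rna_to_dna

    with open(path, "w") as fh:
        fh.write("cluster_id\tmotif_rna\tmotif_dna\tposition\trank\n")
        for a in assignments:
            motif_rna = a.motif or "none"
            motif_dna = rna_to_dna(a.motif) if a.motif else "none"
            pos = "" if a.position is None else a.position
            rank = "" if a.rank is None else a.rank
            fh.write(
                f"{a.cluster_id}\t{motif_rna}\t{motif_dna}\t{pos}\t{rank}\n"
            )


def write_hexamer_tsv(
    dists: Mapping[str, HexamerDistribution], path, top_k: int = 20
) -> None:
    """Top-k hexamers by peak score, one row per (hexamer, position)."""
    ranked = sorted(
        dists.values(), key=lambda d: (-d.peak_score, -d.total, d.hexamer)
    )[:top_k]
    with open(path, "w") as fh:
        fh.write("hexamer\tposition\tcount\tpeak_score\tis_signal\n")
        for d in ranked:
            for pos, cnt in zip(d.positions, d.counts):
                fh.write(
                    f"{d.hexamer}\t{pos}\t{cnt}\t{d.peak_score:.4f}\t"
                    f"{int(d.is_signal)}\n"
                )
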