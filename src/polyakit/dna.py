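"""Small sequence utilities used throughout the pipeline.

All genomic coordinates in this package are 0-based. A cleavage site is a
between-base coordinate: the index of the first genomic base NOT included in
the transcript on the sense strand. For a plus-strand transcript covering
[s, e) the cleavage site is e; for a minus-strand transcript covering [s, e)
it is s (the base at s is the last transcribed base read 3'->5' genomically).
"""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe, case-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)


def dna_to_rna(seq: str) -> str:
    """Report DNA in the RNA alphabet (T->U); padding N passes through."""
    return seq.replace("T", "U").replace("t", "u")


def rna_to_dna(seq: str) -> str:
    return seq.replace("U", "T").replace("u", "t")


def leading_run(seq: str, base: str) -> int:
    """Length of the uninterrupted run of `base` at the start of `seq`."""
    n = 0
    for ch in seq:
        if ch != base:
            break
        n += 1
    return n


def trailing_run(seq: str, base: str) -> int:
    """Length of the uninterrupted run of `base` at the end of `seq`."""
    n = 0
    for ch in reversed(seq):
        if ch != base:
            break
        n += 1
    return n


def max_run(seq: str, base: str) -> int:
    """Length of the longest uninterrupted run of `base` anywhere in `seq`."""
    best = cur = 0
    for ch in seq:
        if ch == base:
            cur += 1
            if cur > best:
                best = cur
        else:
            cur = 0
    return best
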