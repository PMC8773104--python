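"""Quality filtering, terminal poly(A)/poly(T) tail detection and
orientation of reads to the sense strand.

A read is evidence of a cleavage event when it ends with a run of >= 10 A
(sense orientation) or begins with a run of >= 10 T (antisense orientation:
the read is the reverse complement of the transcribed fragment). Runs must
be uninterrupted; N breaks a run. After trimming the full run, antisense
reads are reverse-complemented, so every emitted read's 3' end abuts the
cleavage site.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Optional

from Bio import SeqIO

from .dna import leading_run, revcomp, trailing_run
from .errors import MalformedRecordError

DEFAULT_MIN_RUN = 10
DEFAULT_Q_THRESHOLD = 20
DEFAULT_MIN_FRACTION = 0.8
DEFAULT_MIN_MAPPABLE = 20

PHRED_OFFSET = 33


@dataclass(frozen=True)
class ReadRecord:
    read_id: str
    sequence: str
    quality: Optional[str] = None  # Phred+33; None for FASTA (EST) input


@dataclass(frozen=True)
class TailCall:
    """A qualifying terminal homopolymer run.

    side '3' with base A means a sense-oriented read; side '5' with base T
    means the read must be reverse-complemented (antisense). 5'-A and 3'-T
    configurations are not tails.
    """

    side: str           # '5' or '3'
    base: str           # 'A' or 'T'
    run_length: int
    trimmed_sequence: str
    orientation: str    # 'sense' or 'antisense'


def read_input(path, fmt: Optional[str] = None) -> Iterator[ReadRecord]:
    """Stream FASTQ (Phred+33) or FASTA records as ReadRecords."""
    path = str(path)
    if fmt is None:
        fmt = "fastq" if path.endswith(("fastq", "fq")) else "fasta"
    for rec in SeqIO.parse(path, fmt):
        qual = None
        if fmt == "fastq":
            qual = "".join(
                chr(q + PHRED_OFFSET)
                for q in rec.letter_annotations["phred_quality"]
            )
        yield ReadRecord(rec.id, str(rec.seq).upper(), qual)


def quality_filter(
    read: ReadRecord,
    q_threshold: int = DEFAULT_Q_THRESHOLD,
    min_fraction: float = DEFAULT_MIN_FRACTION,
) -> bool:
    """Keep iff >= min_fraction of bases have quality >= q_threshold.

    The boundary is inclusive (exactly min_fraction passes). FASTA records
    (no qualities) bypass the filter and are kept.
    """
    if read.quality is None:
        return True
    if len(read.quality) != len(read.sequence):
        raise MalformedRecordError(
            f"read {read.read_id}: sequence length {len(read.sequence)} != "
            f"quality length {len(read.quality)}"
        )
    if not read.sequence:
        return False
    good = sum(
        1 for q in read.quality if ord(q) - PHRED_OFFSET >= q_threshold
    )
    return good >= min_fraction * len(read.sequence) - 1e-9


def clip_adapter(read: ReadRecord, adapter: Optional[str]) -> ReadRecord:
    """Remove the first exact adapter occurrence and everything 3' of it."""
    if not adapter:
        return read
    pos = read.sequence.find(adapter.upper())
    if pos < 0:
        return read
    qual = read.quality[:pos] if read.quality is not None else None
    return ReadRecord(read.read_id, read.sequence[:pos], qual)


def detect_tail(
    sequence: str, min_run: int = DEFAULT_MIN_RUN
) -> Optional[TailCall]:
    """Detect a terminal poly(A) (3') or poly(T) (5') run of >= min_run.

    When both ends qualify the longer run wins; an exact tie prefers the
    3'-A call (the canonical library orientation).
    """
    if not sequence:
        return None
    a3 = trailing_run(sequence, "A")
    t5 = leading_run(sequence, "T")
    a_ok = a3 >= min_run
    t_ok = t5 >= min_run
    if not a_ok and not t_ok:
        return None
    if a_ok and (not t_ok or a3 >= t5):
        return TailCall("3", "A", a3, sequence[:-a3], "sense")
    return TailCall("5", "T", t5, sequence[t5:], "antisense")


def trim_and_orient(
    read: ReadRecord,
    tail: TailCall,
    min_mappable: int = DEFAULT_MIN_MAPPABLE,
) -> Optional[ReadRecord]:
    """Remove the tail run and orient the remainder to the sense strand.

    Antisense reads are reverse-complemented (qualities reversed). Reads
    shorter than min_mappable after trimming are discarded (None).
    """
    seq = tail.trimmed_sequence
    if len(seq) < min_mappable:
        return None
    if tail.orientation == "antisense":
        seq = revcomp(seq)
        qual = read.quality[tail.run_length:][::-1] if read.quality else None
    else:
        qual = read.quality[: len(seq)] if read.quality else None
    return ReadRecord(read.read_id, seq, qual)


@dataclass
class ProcessingCounts:
    input: int = 0
    quality_discarded: int = 0
    no_tail: int = 0
    too_short: int = 0
    emitted: int = 0

    def as_dict(self) -> dict[str, int]:
        return {
            "input": self.input,
            "quality_discarded": self.quality_discarded,
            "no_tail": self.no_tail,
            "too_short": self.too_short,
            "emitted": self.emitted,
        }


def process_reads(
    reads: Iterable[ReadRecord],
    min_run: int = DEFAULT_MIN_RUN,
    q_threshold: int = DEFAULT_Q_THRESHOLD,
    min_fraction: float = DEFAULT_MIN_FRACTION,
    min_mappable: int = DEFAULT_MIN_MAPPABLE,
    adapter: Optional[str] = None,
) -> tuple[list[ReadRecord], list[TailCall], ProcessingCounts]:
    """Full read-processing stage: filter, clip, detect tails, orient.

    Returns oriented trimmed reads, their tail calls (parallel list) and
    per-stage counts.
    """
    counts = ProcessingCounts()
    oriented: list[ReadRecord] = []
    calls: list[TailCall] = []
    for read in reads:
        counts.input += 1
        if not quality_filter(read, q_threshold, min_fraction):
            counts.quality_discarded += 1
            continue
        read = clip_adapter(read, adapter)
        tail = detect_tail(read.sequence, min_run)
        if tail is None:
            counts.no_tail += 1
            continue
        trimmed = trim_and_orient(read, tail, min_mappable)
        if trimmed is None:
            counts.too_short += 1
            continue
        counts.emitted += 1
        oriented.append(trimmed)
        calls.append(tail)
    return oriented, calls, counts


def write_tail_table(reads, calls, path) -> None:
    """TSV sidecar: read id, side, base, run_length, orientation."""
    with open(path, "w") as fh:
        fh.write("read_id\tside\tbase\trun_length\torientation\n")
        for read, call in zip(reads, calls):
            fh.write(
                f"{read.read_id}\t{call.side}\t{call.base}\t"
                f"{call.run_length}\t{call.orientation}\n"
            )


def write_oriented_fasta(reads: Iterable[ReadRecord], path) -> None:
    with open(path, "w") as fh:
        for read in reads:
            fh.write(f">{read.read_id}\n{read.sequence}\n")
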