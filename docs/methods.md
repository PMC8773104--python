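# Methods

## Coordinate conventions

All internal coordinates are 0-based. A cleavage site is a *between-base*
coordinate: the index of the first genomic base not included in the
transcript on the sense strand. A plus-strand alignment covering
[start, end) therefore cleaves at `end`; a minus-strand alignment cleaves
at `start`. Context windows are 200 nt, indices −100..+99 with the CS at 0:
index 0 holds the first base downstream of cleavage and index −1 the last
transcribed base. For minus-strand sites the window is the reverse
complement of `genome[pos−100 : pos+100]`, which makes plus and minus
contexts exactly mirror-symmetric. Hexamer start positions consequently
span −100..+94. GFF3 and SAM are read/written 1-based per their standards.

## Read processing

A read is kept when ≥ 80% of its bases reach Q20 (both thresholds
configurable; FASTA/EST input bypasses the filter). Tails are maximal
uninterrupted terminal runs — ≥10 A at the 3′ end (sense) or ≥10 T at the
5′ end (antisense); N breaks a run and never counts toward one. 5′-A and
3′-T configurations are not tails. When both ends qualify the longer run
wins and an exact tie prefers the 3′-A call, the canonical library
orientation. The full run is trimmed, antisense reads are
reverse-complemented, and remainders shorter than 20 nt (`min_mappable`)
are dropped: the value balances specificity against yield on the small
synthetic genomes the built-in aligner targets.

## Alignment and site calling

The built-in aligner is an exact-match seeded search (20-mer seed table,
full-length verification, both strands) intended for genomes up to a few
megabases; only reads with exactly one full-length occurrence are kept, so
reads carrying a substitution drop out as unmapped rather than mapping
approximately. Real data should be aligned externally and imported as SAM,
where unmapped, secondary, supplementary and MAPQ-0 records are dropped
and reference ends honour the CIGAR. EST and RNA-seq streams are processed
identically and merged at the site level before clustering.

The internal-priming filter inspects the 20 nt of sense-strand genomic
sequence immediately downstream of each CS (for minus-strand sites, the
reverse complement of the upstream genomic window) and removes the site if
it contains ≥8 consecutive A. The filter is applied to the sense strand
only: after orientation, a genomic A-run is precisely what can mimic a
tail, while a sense-strand T-run cannot; the minus-strand case is the
mirror image already handled by orientation. The 20 nt window length is a
package choice — it must at least contain an 8-run and covers the region
an oligo(dT) primer would anneal to — and is configurable.

Clustering is single-linkage chaining over position-sorted sites per
(chromosome, strand): consecutive sites ≤20 bp apart join one cluster, so
a chain may span more than 20 bp overall while every adjacent pair is
within the threshold; the span is reported alongside. The representative
is the member with the highest read support, ties resolving to the
smallest position. The partition is order-invariant and conserves support.

## Signal analysis

Profiles report per-position symbol frequencies over non-padded contexts
in the RNA alphabet (A/C/G/U; file outputs also carry DNA). The hexamer
scan counts, for each of the 4096 hexamers, the contexts containing it at
each start position. The peak statistic is

    score = mean count/position in the signal window (−30..−11 starts)
          / max(mean count/position in the background window (+20..+94), 0.5)

with `is_signal = score ≥ 3 and total ≥ 0.5% of contexts`. The windows,
threshold, minimum and 0.5 pseudo-count are package-defined (peak-vs-
scatter judgments are otherwise visual in the literature) and all
configurable. The signal window is where a PAS body at 10–30 nt upstream
of the CS places hexamer starts; the background window sits downstream of
the U/GU element.

PAS assignment scans a 14-motif hierarchy (AAUAAA, then the single-base
variants in descending published frequency) for occurrences whose start
lies in −40..−6, i.e. the motif body fully inside the 40 nt upstream of
the CS. The first motif in hierarchy order with an occurrence wins;
among its occurrences the most 3′ (closest to cleavage) is recorded.
Frequency-rank priority is the standard disambiguation convention when
several motifs co-occur.

## APA annotation

Gene models are the union of features over transcripts, which is
deterministic and robust to annotation versions; introns are the gaps of
the exon union. A cluster is assigned to a gene when its representative
position lies in the gene span or in a strand-aware 2 kb 3′ extension
(compensating for incomplete UTR annotation), same strand only; among
overlapping candidates the gene with the nearest annotated 3′ end wins.
Feature classification uses the last transcribed base (position − 1 on
plus, position on minus) with precedence 3′UTR > 5′UTR > exon(CDS) >
intron where isoform intervals overlap — collisions resolve toward the
biologically expected class. Positions in the extension carry the
distinct class `extended-3'` internally and are reported under 3′UTR,
since the transcript terminus there is by construction a 3′ end.

## The simulator

`SimConfig` defaults define the standard study fixture: 2 chromosomes ×
250 kb of uniform-composition sequence, 200 compact genes (2–4 exons,
alternating strands, non-overlapping), 1–5 pA clusters per gene (uniform;
expected ~600 clusters, 80% of genes with ≥2 sites), 100,000 reads of
80 nt, per-base error 0.002, 5% internally primed reads, 5% tail-less
background reads and 1% uniformly low-quality reads.

Per cluster the simulator plants, on the sense strand relative to the
representative CS:

* a PAS hexamer drawn from the published frequency table (probabilities
  normalized to sum to 1; ~10.6% of clusters get none), starting at
  −d with d ~ round(Normal(16, 3)) clipped to [10, 30] — the biological
  10–30 nt upstream placement; the true offset distribution is unknown,
  so the Normal is a modeling choice;
* the CA cleavage dinucleotide at −1..0 of **every** member cleavage
  position (CA is the canonical cleavage context of each cleavage event;
  this also pins the base preceding each member so tail trimming cannot
  slide into templated genomic A);
* a U/GU-rich downstream element (T 0.55 / G 0.30 / C 0.10 / A 0.05) at
  +5..+25.

Member cleavage positions (1, 2 or 3 per cluster at the published
heterogeneity fractions, all ">2" mass on 3) sit within ±10 nt of the
representative, pairwise ≥2 nt apart so the planted CA dinucleotides are
disjoint, and clear of the motif body. Clusters within a gene are ≥80 nt
apart; the placement window runs from 40 nt into the 3′UTR to 200 nt past
the annotated 3′ end, and intergenic gaps are ≥600 nt, so planted elements
of different clusters can never collide. Internal-priming decoys are
genomic A-runs (T-runs for minus-sense decoys) of 10–15 nt planted in
introns and intergenic space with pinned boundaries; decoy reads end at
the far end of the run so the run itself is their false tail. Cluster
reads are sense fragments ending exactly at a member position (the
representative drawing 60% of a cluster's reads) plus a pure poly(A) tail
of 12–35 nt; half of all reads are emitted reverse-complemented.
Substitution errors are applied after orientation flipping. All stages
draw from generators derived from a single seed, and identical
configurations reproduce byte-identical FASTA/FASTQ/GFF3/TSV outputs.

What the simulator does **not** model: transcript-abundance variation
(reads are uniform over clusters), paired ends, spliced reads (fragments
are genome-contiguous, adequate because trimmed reads are mapped
genomically), indels, quality-score gradients within reads, and repeat
structure in the genome background. Passing recovery tests therefore
demonstrates the correctness of the pipeline's logic under its stated
assumptions, not robustness to mappability or abundance pathologies of
real transcriptomes.

## Numerical and degenerate-input choices

Percentages are reported over all clusters and sum to 100 ± 0.1 after
rounding. Heterogeneity fractions of an empty cluster set are reported as
undefined rather than 0/0. Context windows truncated at chromosome ends
are N-padded and excluded from profile denominators. Empty context sets
and empty assignment sets raise errors rather than returning silent
zeros. Motif placements that would overwrite an already planted element
are re-drawn up to 10 times, then skipped with a logged warning and the
cluster recorded as motif-free (collisions are geometrically impossible
under the default layout; the guard covers tight custom configurations).

## Known limitations

* Sequencing errors at the base adjacent to a tail can shift a read's
  inferred CS by one base, creating rare low-support satellite members;
  at the default error rate this biases recovered heterogeneity fractions
  by a few percent, within the tolerance the recovery tests allow — the
  same mechanism operates in real data.
* The exact-match aligner discards every read carrying an error, so
  effective coverage is `(1 − error_rate)^read_length` of the input;
  this is intentional for the synthetic setting and irrelevant to the SAM
  path.
* `none`-class PAS frequencies are biased downward by chance occurrences
  of listed motifs in random flanks; recovery tests correct for this with
  a Monte-Carlo estimate from motif-free simulated contexts.
* Problem sizes in the test suite (the 200-gene / 100,000-read fixture,
  10,000-context motif experiments, 10,000-case oracle comparisons) were
  chosen to give 3-SD binomial resolution of a few percent on every
  recovered parameter while keeping the suite fast.
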