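# polyakit

Identification of poly(A) cleavage sites, polyadenylation-signal (PAS)
motif analysis and alternative-polyadenylation (APA) annotation from
tail-bearing sequencing reads (RNA-seq or EST), together with a fully
synthetic benchmarking harness with planted ground truth.

## The problem

Cleavage and polyadenylation define the 3′ end of almost every eukaryotic
mRNA. Reads that retain part of the non-templated poly(A) tail pinpoint the
cleavage site (CS) at single-base resolution: a read ending in a run of ≥10
A (or beginning with ≥10 T, when sequenced from the opposite strand) is
trimmed, oriented to the sense strand, and mapped; its 3′ end is the CS.
Two artifacts must be controlled:

* **Internal priming** — oligo(dT) annealing to a genomic A-run mimics a
  tail. A CS whose downstream genomic window (20 nt) contains ≥8
  consecutive A on the sense strand is discarded.
* **Microheterogeneity** — cleavage wobbles over a few bases. Cleavage
  sites separated by ≤20 bp are merged into one **pA cluster** by
  single-linkage chaining; the member with the highest read support is the
  cluster's representative position.

Around each cluster, the package extracts a ±100 nt sense-strand context
(CS at position 0), computes positional mono- and dinucleotide profiles
(the CA cleavage dinucleotide at −1..0, the U/GU-rich downstream element),
scans all 4096 hexamers for positionally peaked signals, and assigns each
cluster one of the 14 canonical PAS hexamers (AAUAAA first, then the
variants in descending frequency order) found within the 40 nt upstream of
the CS — or `none`. Clusters are then assigned to annotated genes (gene
span plus a 2 kb 3′ extension, same strand, nearest 3′ end on ties),
classified by feature (3′UTR > 5′UTR > exon(CDS) > intron), and summarized
per gene to quantify APA usage.

Because real inputs at corpus scale are impractical to ship, the package
includes a first-class simulator that plants all of this structure —
genes with UTRs on both strands, pA clusters with configurable PAS motif
frequencies, cleavage heterogeneity, poly(A)/poly(T) tails, sequencing
errors and internal-priming decoys — so every stage is testable against
known truth.

## Worked example

```bash
polyakit simulate --seed 7 --out fx --n-genes 30 --n-reads 8000 --chrom-length 100000
polyakit run --genome fx/genome.fa --reads fx/reads.fastq \
             --gff3 fx/annotation.gff3 --out out
polyakit report --summary out/summary.json
```

prints (abridged):

```
== stage counts ==
raw_reads                    8000
tail_containing              7362
uniquely_mapped              6404
cleavage_sites               290
internal_priming_removed     60
pa_clusters                  104
== cleavage-site heterogeneity ==
  1 member(s):  28.85%
  2 member(s):  23.08%
 >2 member(s):  48.08%
== PAS motif frequency (%) ==
AAUAAA    50.00
AUUAAA    13.46
none      13.46
== APA annotation ==
genic fraction: 1.0000
3'UTR        100.00%
genes with >=2 sites: 0.9667
```

Reading this: of 8,000 simulated reads, 7,362 carried a qualifying
poly(A)/poly(T) run and 6,404 mapped uniquely after trimming; their 3′
ends collapse to 290 distinct cleavage sites, of which 60 were removed as
internal-priming artifacts; the survivors merge into 104 pA clusters.
Half of the clusters carry the canonical AAUAAA signal in their upstream
40 nt (the simulator's default planting frequency is 50.96%), all clusters
fall in 3′UTRs or the 2 kb extension, and ~97% of genes in this small
fixture use two or more pA sites.

Each pipeline stage is also available separately (`filter-reads`,
`call-sites` — which accepts an external SAM of pre-aligned trimmed reads —
`profile`, `pas`, `annotate`), and the whole pipeline is a library call:

```python
from polyakit import PipelineConfig, run_pipeline
summary = run_pipeline(PipelineConfig(genome_fasta=..., reads=..., gff3=...))
```

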