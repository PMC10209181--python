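# sciso — single-cell long-read isoform analysis

`sciso` analyses full-length cDNA long reads (PacBio/ONT-style) from
10x Chromium single-cell libraries, where short-read sequencing defines
the cells and clusters and the long reads reveal which *isoforms* each
cell expresses. It is aimed at people who have a cell-barcode whitelist
with cluster labels (e.g. from a Seurat analysis of the matched
short-read data) plus spliced long-read alignments, and want per-cell,
per-cluster isoform quantification together with annotation-free
discovery of new exons, transcripts and V(D)J-recombined
immunoglobulin messages.

## What it computes

**Demultiplexing.** Each read, on its sense strand, is assumed to carry
`[16 nt cell barcode][10 nt UMI][polyT][reverse-complemented cDNA]`.
Orientation is fixed by locating the polyT (or mirror polyA) tail, the
barcode is corrected against the whitelist by Hamming distance with up
to *hdist* = 3 mismatches over the 16-mer (*k* = 16), ties are dropped
as ambiguous, and the UMI is taken verbatim.

**Isoform assignment.** A read's identity is its ordered chain of splice
junctions in genome space, after junctions within 5 nt of an annotated
junction are snapped onto it (microindel correction). Alignments must
reach identity ≥ 0.9 and query coverage ≥ 0.8. A read is a
*full splice match* (FSM) when its chain equals a transcript's chain, an
*incomplete splice match* (ISM) when it is a contiguous sub-chain (the
usual 5′-truncated read of an oligo-dT library), and otherwise a novel
combination / novel junction / antisense / intergenic read. Reads
collapse to molecules by (barcode, gene, UMI); molecules are tabulated
into a sparse cells × transcripts `AnnData` and summarised as
per-cluster isoform frequencies
freq(t | cluster, gene) = n(t) / Σ_t′ n(t′).

**Novel exons.** An unannotated exon shows up twice: as an insertion of
≥ 21 nt at an exon–exon junction of the transcriptome alignment, and as
an aligned block strictly inside the corresponding intron of the genome
alignment. Candidates confirmed by ≥ 2 distinct reads and overlapping
no known exon become calls; novel junction chains are collapsed into
transcript models, labelled with a splicing event (cassette exon,
alt 5′/3′ splice site, novel junction combination, intron retention),
filtered by support (≥ *N* = 5 reads over ≥ *K* = 3 samples), and
assessed for coding potential by frame preservation: an event inside
the CDS is coding iff its net length change is divisible by 3 and the
modified CDS translates without a premature stop.

**VJ recombination.** V and J segment sequences are matched into reads
by k-mer seeding plus infix alignment (edlib); a read is called
VJ-recombined when its best V hit (matched length ≥ 9) lies upstream of
its best J hit on the cDNA sense strand — the layout produced by V→J
somatic recombination, normally restricted to lymphoid cells.

**Synthetic data.** `sciso.synth` generates a toy genome, a
multi-isoform annotation with labelled splicing events, Dirichlet
per-cluster isoform mixtures, barcoded error-bearing reads with 5′
truncation, planted intronic exons and planted VJ molecules — with full
ground truth, so every stage of the pipeline is testable end to end.

## Worked example

```sh
sciso demo --outdir demo_out --seed 42
```

runs the full pipeline on the synthetic demo (200 cells, 5 clusters,
30 genes, 50 molecules per cell, 1% substitution errors, 5′ truncation
tuned to ~74% mean transcript coverage, 5 planted novel exons, 30
planted VJ molecules). The report it prints includes:

```
total reads: 10047
categories:  {'incomplete_splice_match': 6247, 'full_splice_match': 3753, 'novel_junction': 17}
molecules:   {'total': 10000, 'reads_backing_molecules': 10000}
medians:     {'median_n_reads': 50.0, 'median_n_molecules': 50.0, 'median_n_distinct_transcripts': 31.0}
multi-isoform genes: {'numerator': 24, 'denominator': 30, 'value': 0.8}
novel exons: {'n_calls': 5}
vj reads per cluster: {'cluster1': 7, 'cluster2': 8, 'cluster3': 5, 'cluster4': 6, 'cluster5': 4}
```

Reading this: all 10,047 reads demultiplexed (the synthetic whitelist is
separation-guaranteed; real data assigns far fewer); the 10,000
transcript molecules all survived UMI collapse; truncation makes ~62%
of reads incomplete splice matches while their 3′-anchored junctions
still identify the transcript; 24 of 30 genes show ≥ 2 expressed
isoforms; all 5 planted exons are recovered and all 30 planted VJ
molecules are called (split across clusters). `demo_out/` holds the
matrix (10x-style MTX triplet), per-cluster isoform frequencies,
novel-exon BED, augmented GTF, VJ presence table, a JSON report and a
run manifest.

The same stages are available separately (`sciso synth`, `sciso demux`,
`sciso quant`, `sciso novelty`, `sciso igdetect`, `sciso run`) and as
library functions.

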