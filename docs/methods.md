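# Methods

This note documents the models, thresholds and design choices behind
`sciso`, and what the synthetic experiments do and do not demonstrate.

## Read model and demultiplexing

A library molecule is modelled on its sense strand as

    [16 nt cell barcode][10 nt UMI][30 nt polyT][reverse-complement of the cDNA]

(10x Chromium 3′ v2 chemistry). Reads are sequenced from a uniformly
random strand. Demultiplexing proceeds in three steps:

1. **Orientation.** A polyT run is sought starting within 8 nt after
   the putative barcode/UMI prefix (the slack absorbs small synthesis
   artefacts); the mirror search on the reverse complement detects
   antisense reads. A run qualifies when it is ≥ 20 nt long with a
   non-T fraction ≤ 0.1. The run's 3′ end is then fixed greedily:
   extension continues through T's and steps over an isolated mismatch
   only when two T's follow. This local rule stops at the tail/cDNA
   boundary; the earlier "largest qualifying window" rule crept several
   bases into the insert whenever sparse T's followed the tail. The
   boundary is still ambiguous by nature when a transcript genuinely
   ends in adenosines; downstream steps tolerate a few clipped bases.
2. **Barcode correction.** The observed 16-mer is compared with every
   whitelist barcode; a read is assigned when a unique entry attains the
   minimum Hamming distance and that distance is ≤ 3 (`max_hamming`).
   `N` mismatches everything. Ties are dropped as ambiguous rather than
   broken arbitrarily — a misassigned read contaminates another cell's
   counts, an unassigned read only loses depth. The production matcher
   is a vectorised NumPy distance computation; a plain exhaustive scan
   is kept in the code base purely as its oracle, and the two are
   asserted equal read-by-read in the tests.
3. **UMI.** Taken verbatim, no error correction: at a 1% substitution
   rate ~10% of UMIs carry an error, which splits a molecule into two
   rather than merging distinct molecules; with ~10⁶ possible 10-mers
   per (cell, gene), spurious merges are the rarer failure mode. The
   resulting small upward bias in molecule counts is accepted and
   visible in the tests (molecule counts are exact only because the
   synthetic UMI space is sparse).

## Isoform assignment

Alignments (SAM, genome space) pass a per-read filter of identity ≥ 0.9
and query coverage ≥ 0.8, with identity taken from the `NM` tag when
present and from CIGAR arithmetic otherwise. Before classification,
deletion gaps < 5 nt (`microindel_max`) are absorbed into their
flanking blocks and every splice junction within 5 nt (both ends) of an
annotated junction is snapped onto it. Snapping is idempotent and never
moves a junction across a block boundary.

Classification is by junction chain: FSM (chain equals a transcript's),
ISM (contiguous sub-chain, inside the transcript's span), novel
combination (all junctions annotated, chain new), novel junction
(≥ 1 unannotated junction), antisense (only opposite-strand overlap),
intergenic, unassigned (filter failures and equal-score multi-locus
ties). The cDNA strand on the genome is derived from the demux
orientation combined with the SAM reverse flag, which is what makes the
antisense call possible at all. ISM ties are resolved toward the
transcript sharing the most junctions, then the fewest total junctions,
then the lexicographically smallest id — deterministic, and immaterial
to gene-level molecule counts. Molecules are (barcode, gene, UMI)
groups; the representative transcript is the modal transcript of the
group with lexicographic tie-break.

## Novel exons and transcripts

The two-pass exon discovery mirrors how an unannotated exon manifests:
in transcriptome space as an insertion ≥ 21 nt whose insertion point
lies within ± 5 nt of an exon–exon junction (mid-exon insertions are
artefacts of a different kind and excluded), and in genome space as an
aligned block strictly inside the intron that junction spans. Blocks
whose ends agree within 5 nt are merged (modal interval as the
representative); calls need ≥ 2 distinct supporting reads (read ids,
not alignments, so supplementary records cannot double-count) and must
overlap no exon of the known annotation.

Novel junction chains collapse into one model per chain. The event
label is computed against the annotated isoform sharing the most
junctions, testing in order: intron retention (a provenance junction
spanned by one read block), cassette exon — both the *skip* direction
(two consecutive junctions fused) and the *inclusion* direction (one
junction split in two around a new block); the latter is not a separate
label because a newly included exon is what the field calls a novel
cassette exon — then single-junction analysis (both ends annotated →
novel junction combination; donor/acceptor moved → alt 5′/alt 3′,
strand-aware), with novel junction as the residual. The order makes
the labelling total and unambiguous.

The support filter `N = 5 reads in K = 3 samples` is ambiguous between
"≥ 5 reads in each of ≥ 3 samples" and "≥ 5 reads total across ≥ 3
samples". Both are implemented; the default is the weaker total
reading (≥ N total and ≥ K samples with ≥ 1 read), with the per-sample
reading behind `mode="per_sample"`. Retention is monotone in both N
and K under either mode, and the tests assert that.

**Coding potential** is frame preservation only: an event entirely
outside the provenance CDS inherits the provenance status; otherwise
the net exonic length change within the CDS must be divisible by 3 and
the modified CDS must translate without a premature stop. No
hexamer/logistic scoring is attempted; a learned coding-potential model
is orthogonal to this package's scope.

**Internal priming** is flagged (never removed) when the 20 genomic
bases (`twindow`) past a read's 3′ alignment end are all adenosines on
the cDNA strand.

## VJ detection

Segments are found by exact 11-mer seeding followed by infix
(free-end-gap) edit-distance alignment of the full segment into the
read (edlib), on both strands, with hits reported in the orientation
with the greater total matched length. Hits need identity ≥ 0.8 and the
class minimum matched length (V ≥ 9 nt, J ≥ 0 nt — the J floor is kept
at its conventional value of zero; the identity floor and
whole-segment alignment are what keep the false-call rate at zero on
10⁴ random reads). Segments shorter than 50 nt skip seeding and are
always aligned: a few clustered errors can erase every exact 11-mer of
a 38-nt J segment, and aligning a handful of short segments costs
microseconds. A call requires the best V hit upstream of the best J
hit; end overlaps ≤ 5 nt are tolerated because infix alignment jitters
hit boundaries by a base or two exactly at the recombination junction
(a strict non-overlap rule demonstrably drops true calls there).

## The synthetic generator

The generator is the package's test bed, not a sequencer model. It
emulates: multi-exon genes (3–10 exons of 100–300 nt, introns
100–600 nt) on one chromosome; alternative isoforms derived from a
primary transcript by exactly one labelled event; stop-free CDSs for
coding genes (written directly into the genome as codons); cluster
isoform mixtures drawn from a symmetric Dirichlet (concentration 1 by
default); two conditions ("young"/"aged" across 4 samples) differing in
the fraction of molecules drawn from noncoding genes (0.10 vs 0.20);
i.i.d. substitution errors (1% by default, barcode and UMI included);
and 5′-only truncation — with probability 0.8 a uniform fraction up to
0.65 of the transcript is removed, giving a mean transcript coverage of
1 − 0.8·0.325 ≈ 0.74, typical of oligo-dT full-length libraries.
Error-free truth alignments are emitted against both the genome and the
transcriptome with the barcode/UMI/polyT prefix soft-clipped.

Deliberately *not* modelled: indel errors (barcode matching is
Hamming-based, as the mismatch-budget semantics imply), PCR duplicates
(one read per molecule, so read/molecule conservation is exact),
chimeras, fragment-length distributions, realistic whitelists (the
synthetic whitelist enforces pairwise distance ≥ 2·max_hamming + 1, so
error correction is unambiguous by construction; ambiguity paths are
exercised by dedicated adversarial fixtures instead). Consequently,
passing tests demonstrate the correctness of the *decision rules* under
their stated assumptions, not the error tolerance of the pipeline on
real base-caller output.

## Problem sizes and statistical checks

The recovery experiments use 200 cells × 50 molecules (10⁴ reads) over
6 genes — six genes so that per-(cluster, gene) depths exceed 200
molecules and the frequency-recovery check actually binds; with many
genes the depth condition is vacuous at this scale. Frequency recovery
is asserted inside simultaneous (Šidák-corrected) 99% binomial bands
across all (cluster, gene, transcript) comparisons: with ~50
comparisons, per-comparison 99% bands would be violated somewhere by
chance about half the time, which would test the random seed rather
than the estimator. A half-width continuity term of 1/n is added for
the discreteness of small counts. The acceptance script reports the
per-comparison 99% CI coverage instead (expected ≈ 99–100%).

## Known limitations

- Gene attribution of novel chains follows shared-junction count; a
  read bridging two overlapping genes is attributed, not split.
- ISM assignment cannot distinguish isoforms that differ only 5′ of
  the truncation point; the matrix records the tie-broken choice.
- `biotype_composition`'s two-proportion z-test treats molecules as
  independent; within-cell correlation is ignored, as in most
  pseudobulk proportion comparisons.
- The GTF reader handles the `gene_id`/`transcript_id`/
  `transcript_biotype` attributes it writes; exotic GTF dialects are
  out of scope.
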