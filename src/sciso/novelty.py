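"""Novel-exon discovery and novel-transcript classification.

Novel exons are found in two passes, mirroring how unannotated cassette
exons show up in a long-read experiment: (1) in transcriptome space, an
unannotated exon appears as an *insertion* of at least ``min_insert_len``
nucleotides whose insertion point coincides with an exon-exon junction of
the matched transcript; (2) in genome space, the same read must carry an
aligned block strictly inside the intron that the junction spans.
Confirmed blocks are merged across reads, must reach ``min_exon_support``
distinct reads, and are discarded when they overlap any exon of the known
annotation.

Reads whose junction chain matches no annotated isoform are collapsed by
chain into candidate novel transcripts, labelled with a single splicing
event against the annotated isoform sharing the most junctions, filtered
by read support across samples, and assessed for coding potential by
frame preservation of the provenance CDS.
"""

from __future__ import annotations

import logging
from bisect import bisect_left
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

from Bio.Seq import Seq

from .config import DEFAULT_CONFIG, PipelineConfig
from .models import (
    ALT_3SS,
    ALT_5SS,
    CASSETTE_EXON,
    INTRON_RETENTION,
    NOVEL_COMBINATION,
    NOVEL_JUNCTION,
    NOVEL_JUNCTION_COMBINATION,
    NOVEL_JUNCTION_EVENT,
    Annotation,
    Interval,
    IsoformAssignment,
    NovelExonCall,
    NovelTranscript,
    SplicedAlignment,
    TranscriptModel,
)

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# novel-exon discovery


@dataclass(frozen=True)
class InsertCandidate:
    read_id: str
    transcript_id: str
    query_pos: int
    insert_len: int
    junction_index: int  # 5'->3' junction index on the transcript
    tx_junction_pos: int


def detect_insert_candidates(
    tx_alignments: Iterable[SplicedAlignment],
    annotation: Annotation,
    min_insert_len: int = DEFAULT_CONFIG.min_insert_len,
    tolerance: int = DEFAULT_CONFIG.microindel_max,
) -> list[InsertCandidate]:
    """Insertions of >= ``min_insert_len`` nt at exon junctions of the
    aligned transcript (placement tolerance +/- ``tolerance`` nt);
    mid-exon insertions are excluded."""
    out: list[InsertCandidate] = []
    for aln in tx_alignments:
        if aln.target_kind != "transcriptome":
            continue
        if aln.target_id not in annotation.transcripts:
            continue
        jpos = annotation[aln.target_id].junction_tx_positions()
        if not jpos:
            continue
        for ins in aln.insertions:
            if ins.length < min_insert_len:
                continue
            for jx, p in enumerate(jpos):
                if abs(ins.target_pos - p) <= tolerance:
                    out.append(
                        InsertCandidate(
                            read_id=aln.read_id,
                            transcript_id=aln.target_id,
                            query_pos=ins.query_pos,
                            insert_len=ins.length,
                            junction_index=jx,
                            tx_junction_pos=p,
                        )
                    )
                    break
    return out


def _overlaps_known_exon(chrom: str, start: int, end: int, exons_by_chrom: Mapping[str, list[Interval]]) -> bool:
    exons = exons_by_chrom.get(chrom, [])
    i = bisect_left(exons, (end, end))
    for s, e in exons[max(0, i - 50) : i + 1]:
        if s < end and start < e:
            return True
    return False


def confirm_novel_exons(
    candidates: Sequence[InsertCandidate],
    genome_alignments: Iterable[SplicedAlignment],
    annotation: Annotation,
    min_exon_support: int = DEFAULT_CONFIG.min_exon_support,
    tolerance: int = DEFAULT_CONFIG.microindel_max,
) -> list[NovelExonCall]:
    """Confirm insert candidates against genome-space alignments.

    A candidate is confirmed when its read's genome alignment contains a
    block strictly inside the intron spanned by the junction where the
    insert was seen. Blocks identical after merging within ``tolerance``
    are pooled; calls below ``min_exon_support`` distinct reads or
    overlapping any known exon are discarded.
    """
    by_read: dict[str, SplicedAlignment] = {}
    for aln in genome_alignments:
        if aln.target_kind == "genome":
            by_read.setdefault(aln.read_id, aln)

    confirmed: list[tuple[str, Interval, str, Interval, str]] = []  # chrom, block, gene, intron, read
    for cand in candidates:
        aln = by_read.get(cand.read_id)
        if aln is None:
            logger.warning("novel-exon candidate read %s has no genome alignment; dropped", cand.read_id)
            continue
        t = annotation[cand.transcript_id]
        n_junc = len(t.junctions)
        jx_gen = cand.junction_index if t.strand == "+" else n_junc - 1 - cand.junction_index
        intron = t.junctions[jx_gen]
        for s, e in aln.blocks:
            if intron[0] < s and e < intron[1]:
                confirmed.append((t.chrom, (s, e), t.gene_id, intron, cand.read_id))
                break

    # merge blocks whose ends agree within the snapping tolerance
    groups: list[dict] = []
    for chrom, block, gene, intron, read_id in sorted(confirmed):
        placed = False
        for g in groups:
            if (
                g["chrom"] == chrom
                and g["gene"] == gene
                and abs(g["block"][0] - block[0]) <= tolerance
                and abs(g["block"][1] - block[1]) <= tolerance
            ):
                g["reads"].add(read_id)
                g["votes"].append(block)
                placed = True
                break
        if not placed:
            groups.append(
                {"chrom": chrom, "block": block, "gene": gene, "intron": intron, "reads": {read_id}, "votes": [block]}
            )

    exons_by_chrom = annotation.all_known_exons()
    calls: list[NovelExonCall] = []
    for g in groups:
        votes = sorted(g["votes"])
        rep = max(set(votes), key=lambda b: (votes.count(b), (-b[0], -b[1])))
        if len(g["reads"]) < min_exon_support:
            continue
        if _overlaps_known_exon(g["chrom"], rep[0], rep[1], exons_by_chrom):
            continue
        calls.append(
            NovelExonCall(
                chrom=g["chrom"],
                start=rep[0],
                end=rep[1],
                gene_id=g["gene"],
                intron=g["intron"],
                read_ids=frozenset(g["reads"]),
            )
        )
    return sorted(calls, key=lambda c: (c.chrom, c.start, c.end))


def write_novel_exon_bed(calls: Sequence[NovelExonCall], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for c in calls:
            frame = "frame_preserving" if c.frame_preserving else "frameshifting"
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{c.gene_id}|{frame}\t{c.n_support}\t.\n")


# --------------------------------------------------------------------------
# novel-transcript classification


def _classify_event(
    chain: tuple[Interval, ...],
    blocks: Sequence[Interval],
    provenance: TranscriptModel,
    annotation: Annotation,
    gene_id: str,
) -> str:
    prov_j = set(provenance.junctions)
    read_j = set(chain)
    removed = sorted(prov_j - read_j)
    added = sorted(read_j - prov_j)

    # intron retention: a provenance junction spanned by one read exon
    for j in removed:
        if any(s <= j[0] and j[1] <= e for s, e in blocks):
            return INTRON_RETENTION
    # skipped annotated exon: two consecutive junctions fused into one
    if len(added) == 1 and len(removed) == 2:
        a, (r1, r2) = added[0], removed
        if a[0] == r1[0] and a[1] == r2[1] and r1[1] <= r2[0]:
            return CASSETTE_EXON
    # included (novel) exon: one junction split in two around a new block
    if len(added) == 2 and len(removed) == 1:
        (a1, a2), r = added, removed[0]
        if a1[0] == r[0] and a2[1] == r[1] and a1[1] < a2[0]:
            return CASSETTE_EXON

    gene_junctions = annotation.gene_junctions(gene_id)
    novel_pairs = [j for j in chain if j not in gene_junctions]
    if not novel_pairs:
        # every junction is annotated somewhere in the gene; the chain is new
        return NOVEL_JUNCTION_COMBINATION
    if len(novel_pairs) == 1:
        j = novel_pairs[0]
        strand = annotation.gene_strand(gene_id)
        lefts, rights = annotation.gene_splice_sites(gene_id)
        donor, acceptor = (j[0], j[1]) if strand == "+" else (j[1], j[0])
        donor_known = donor in (lefts if strand == "+" else rights)
        acceptor_known = acceptor in (rights if strand == "+" else lefts)
        if donor_known and acceptor_known:
            return NOVEL_JUNCTION_COMBINATION
        if acceptor_known and not donor_known:
            return ALT_5SS
        if donor_known and not acceptor_known:
            return ALT_3SS
    return NOVEL_JUNCTION_EVENT


def _model_from_chain(
    chain: tuple[Interval, ...], span: Interval, chrom: str, strand: str, gene_id: str, name: str
) -> TranscriptModel:
    exons = []
    start = span[0]
    for s, e in chain:
        exons.append((start, s))
        start = e
    exons.append((start, span[1]))
    return TranscriptModel(name, gene_id, chrom, strand, tuple(exons), biotype="novel")


def classify_novel_transcripts(
    items: Sequence[tuple[IsoformAssignment, SplicedAlignment]],
    annotation: Annotation,
    sample_of_barcode: Optional[Mapping[str, str]] = None,
) -> list[NovelTranscript]:
    """Collapse novel-category reads by junction chain into transcript
    models, each labelled with one splicing event against the annotated
    isoform sharing the most junctions."""
    sample_of_barcode = dict(sample_of_barcode or {})
    groups: dict[tuple, dict] = {}
    for assignment, aln in items:
        if assignment.category not in (NOVEL_COMBINATION, NOVEL_JUNCTION):
            continue
        if assignment.gene_id is None or not aln.junctions:
            continue
        key = (aln.target_id, assignment.gene_id, aln.junctions)
        g = groups.setdefault(key, {"reads": [], "span": (aln.start, aln.end)})
        g["reads"].append(assignment)
        g["span"] = (min(g["span"][0], aln.start), max(g["span"][1], aln.end))
        g.setdefault("blocks", aln.blocks)

    out: list[NovelTranscript] = []
    for i, (key, g) in enumerate(sorted(groups.items()), start=1):
        chrom, gene_id, chain = key
        txs = annotation.gene_transcripts(gene_id)
        provenance = max(
            txs, key=lambda t: (len(set(t.junctions) & set(chain)), -len(t.junctions), t.transcript_id)
        )
        event = _classify_event(chain, g["blocks"], provenance, annotation, gene_id)
        model = _model_from_chain(
            chain, g["span"], chrom, annotation.gene_strand(gene_id), gene_id, f"NOVEL.{gene_id}.{i}"
        )
        support: dict[str, int] = {}
        read_ids = []
        for a in g["reads"]:
            sample = sample_of_barcode.get(a.barcode, "unknown")
            support[sample] = support.get(sample, 0) + 1
            read_ids.append(a.read_id)
        out.append(
            NovelTranscript(
                model=model,
                event=event,
                support=support,
                provenance=provenance.transcript_id,
                read_ids=tuple(sorted(read_ids)),
            )
        )
    return out


# --------------------------------------------------------------------------
# filtering


def filter_novel_transcripts(
    models: Sequence[NovelTranscript],
    min_reads: int = DEFAULT_CONFIG.min_transcript_reads,
    min_samples: int = DEFAULT_CONFIG.min_transcript_samples,
    mode: str = "total",
) -> list[NovelTranscript]:
    """Support filter for novel transcript models.

    ``mode='total'`` (default): keep models with >= ``min_reads`` reads in
    total and >= ``min_samples`` samples contributing >= 1 read each.
    ``mode='per_sample'``: keep models with >= ``min_samples`` samples
    each contributing >= ``min_reads`` reads.
    """
    if mode not in ("total", "per_sample"):
        raise ValueError(f"bad mode {mode!r}")
    out = []
    for m in models:
        if mode == "total":
            ok = m.total_support >= min_reads and sum(1 for v in m.support.values() if v >= 1) >= min_samples
        else:
            ok = sum(1 for v in m.support.values() if v >= min_reads) >= min_samples
        if ok:
            out.append(m)
    return out


def remove_matched_antisense(
    models: Sequence[NovelTranscript], annotation: Annotation
) -> list[NovelTranscript]:
    """Drop novel models that perfectly mirror an annotated transcript on
    the opposite strand (unreliable mappings)."""
    by_chrom: dict[str, list[TranscriptModel]] = {}
    for t in annotation:
        by_chrom.setdefault(t.chrom, []).append(t)
    out = []
    for m in models:
        mirrored = any(
            t.strand != m.model.strand
            and t.junctions == m.model.junctions
            and t.start < m.model.end
            and m.model.start < t.end
            for t in by_chrom.get(m.model.chrom, [])
        )
        if not mirrored:
            out.append(m)
    return out


# --------------------------------------------------------------------------
# coding assessment


def _exonic_overlap(exons: Sequence[Interval], span: Interval) -> int:
    return sum(max(0, min(e, span[1]) - max(s, span[0])) for s, e in exons)


def _interval_diff(a: Sequence[Interval], b: Sequence[Interval]) -> list[Interval]:
    """Regions exonic in exactly one of the two exon sets."""
    edges = sorted({x for iv in list(a) + list(b) for x in iv})
    out: list[Interval] = []
    for s, e in zip(edges, edges[1:]):
        mid = (s + e) // 2
        in_a = any(x <= mid < y for x, y in a)
        in_b = any(x <= mid < y for x, y in b)
        if in_a != in_b:
            if out and out[-1][1] == s:
                out[-1] = (out[-1][0], e)
            else:
                out.append((s, e))
    return out


def assess_coding(
    model: NovelTranscript,
    annotation: Annotation,
    genome: Mapping[str, str],
) -> Optional[bool]:
    """Frame-preservation coding assessment against the provenance CDS.

    Coding iff the net exonic length change within the CDS is a multiple
    of 3 and the modified CDS translates without a premature stop before
    the annotated one. Events entirely outside the CDS inherit the
    provenance's coding status. Returns None when the provenance
    transcript has no annotated CDS.
    """
    prov = annotation[model.provenance]
    if prov.cds is None:
        model.coding = None
        return None
    t = model.model
    diff = _interval_diff(t.exons, prov.exons)
    cds_span = prov.cds
    if all(e <= cds_span[0] or s >= cds_span[1] for s, e in diff):
        model.coding = True  # UTR-only event inherits provenance (coding) status
        return True

    delta = _exonic_overlap(t.exons, cds_span) - _exonic_overlap(prov.exons, cds_span)
    if delta % 3 != 0:
        model.coding = False
        return False

    cds_tx = prov.cds_tx_interval()
    if cds_tx is None:
        model.coding = None
        return None
    cds_5p_genomic = cds_span[0] if prov.strand == "+" else cds_span[1] - 1
    start_in_model = t.genomic_to_tx(cds_5p_genomic)
    if start_in_model is None:
        model.coding = False  # start codon spliced out
        return False
    new_len = (cds_tx[1] - cds_tx[0]) + delta
    seq = t.spliced_sequence(genome)
    cds_seq = seq[start_in_model : start_in_model + new_len]
    cds_seq = cds_seq[: len(cds_seq) // 3 * 3]
    protein = str(Seq(cds_seq).translate())
    coding = "*" not in protein[:-1]
    model.coding = coding
    return coding


# --------------------------------------------------------------------------
# internal-priming flag


def flag_internal_priming(
    aln: SplicedAlignment,
    genome: Mapping[str, str],
    cdna_strand: str,
    twindow: int = DEFAULT_CONFIG.twindow,
) -> bool:
    """Flag a read whose 3' alignment end is followed by ``twindow``
    genomic adenosines (on the cDNA strand), the signature of oligo-dT
    priming inside the transcript body."""
    chrom_seq = genome[aln.target_id]
    if cdna_strand == "+":
        window = chrom_seq[aln.end : aln.end + twindow]
        return len(window) == twindow and set(window) == {"A"}
    window = chrom_seq[max(0, aln.start - twindow) : aln.start]
    return len(window) == twindow and set(window) == {"T"}


def write_novel_transcripts_tsv(models: Sequence[NovelTranscript], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\tgene_id\tevent\tprovenance\ttotal_support\tn_samples\tcoding\n")
        for m in models:
            coding = "" if m.coding is None else str(m.coding).lower()
            fh.write(
                f"{m.model.transcript_id}\t{m.model.gene_id}\t{m.event}\t{m.provenance}\t"
                f"{m.total_support}\t{len(m.support)}\t{coding}\n"
            )
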