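"""Domain types shared across the pipeline.

Coordinate conventions: all genomic intervals are 0-based half-open
`(start, end)` on the forward strand of the chromosome, regardless of
transcript strand. A *junction* is the intron interval `(donor_end,
acceptor_start)` in those coordinates, i.e. the gap between two adjacent
exons; a transcript's *junction chain* is its ordered tuple of junctions
in genomic order. Transcript ("spliced") coordinates run 5'->3' along the
mature transcript.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .sequence import revcomp

Interval = tuple[int, int]

# Isoform-assignment categories.
FULL_SPLICE_MATCH = "full_splice_match"
INCOMPLETE_SPLICE_MATCH = "incomplete_splice_match"
NOVEL_COMBINATION = "novel_combination"
NOVEL_JUNCTION = "novel_junction"
ANTISENSE = "antisense"
INTERGENIC = "intergenic"
UNASSIGNED = "unassigned"

CATEGORIES = (
    FULL_SPLICE_MATCH,
    INCOMPLETE_SPLICE_MATCH,
    NOVEL_COMBINATION,
    NOVEL_JUNCTION,
    ANTISENSE,
    INTERGENIC,
    UNASSIGNED,
)

# Novel-transcript event labels.
CASSETTE_EXON = "cassette_exon"
ALT_5SS = "alt_5ss"
ALT_3SS = "alt_3ss"
NOVEL_JUNCTION_COMBINATION = "novel_junction_combination"
NOVEL_JUNCTION_EVENT = "novel_junction"
INTRON_RETENTION = "intron_retention"

EVENT_LABELS = (
    CASSETTE_EXON,
    ALT_5SS,
    ALT_3SS,
    NOVEL_JUNCTION_COMBINATION,
    NOVEL_JUNCTION_EVENT,
    INTRON_RETENTION,
)


@dataclass(frozen=True)
class TranscriptModel:
    """One isoform: ordered exons on a chromosome, with optional CDS."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    exons: tuple[Interval, ...]  # sorted by genomic start, non-overlapping
    biotype: str = "protein_coding"
    cds: Optional[Interval] = None  # genomic span of the coding region

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        ex = tuple(sorted(tuple(e) for e in self.exons))
        object.__setattr__(self, "exons", ex)
        for (s1, e1), (s2, e2) in zip(ex, ex[1:]):
            if e1 >= s2:
                raise ValueError(f"{self.transcript_id}: exons overlap or touch: {(s1,e1)} {(s2,e2)}")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> Interval:
        return (self.start, self.end)

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def junctions(self) -> tuple[Interval, ...]:
        """Intron intervals in genomic order."""
        return tuple((a[1], b[0]) for a, b in zip(self.exons, self.exons[1:]))

    @property
    def introns(self) -> tuple[Interval, ...]:
        return self.junctions

    def exons_in_tx_order(self) -> tuple[Interval, ...]:
        return self.exons if self.strand == "+" else tuple(reversed(self.exons))

    def junction_tx_positions(self) -> tuple[int, ...]:
        """Transcript coordinate (5'->3') of each exon/exon boundary."""
        pos, out = 0, []
        for s, e in self.exons_in_tx_order()[:-1]:
            pos += e - s
            out.append(pos)
        return tuple(out)

    def genomic_to_tx(self, gpos: int) -> Optional[int]:
        """Map a genomic position inside an exon to transcript coordinates."""
        off = 0
        for s, e in self.exons_in_tx_order():
            if s <= gpos < e:
                return off + (gpos - s if self.strand == "+" else e - 1 - gpos)
            off += e - s
        return None

    def spliced_sequence(self, genome: Mapping[str, str]) -> str:
        chrom_seq = genome[self.chrom]
        seq = "".join(str(chrom_seq[s:e]) for s, e in self.exons)
        return seq if self.strand == "+" else revcomp(seq)

    def cds_tx_interval(self) -> Optional[Interval]:
        """CDS as a half-open interval in transcript coordinates."""
        if self.cds is None:
            return None
        gs, ge = self.cds
        if self.strand == "+":
            a, b = self.genomic_to_tx(gs), self.genomic_to_tx(ge - 1)
        else:
            a, b = self.genomic_to_tx(ge - 1), self.genomic_to_tx(gs)
        if a is None or b is None:
            return None
        return (a, b + 1)


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    transcripts: tuple[str, ...]


class Annotation:
    """A set of transcript models indexed by transcript, gene and locus."""

    def __init__(self, transcripts: Iterable[TranscriptModel]):
        self.transcripts: dict[str, TranscriptModel] = {}
        self.genes: dict[str, list[str]] = {}
        for t in transcripts:
            if t.transcript_id in self.transcripts:
                raise ValueError(f"duplicate transcript id {t.transcript_id}")
            self.transcripts[t.transcript_id] = t
            self.genes.setdefault(t.gene_id, []).append(t.transcript_id)

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self):
        return iter(self.transcripts.values())

    def __getitem__(self, transcript_id: str) -> TranscriptModel:
        return self.transcripts[transcript_id]

    def gene_transcripts(self, gene_id: str) -> list[TranscriptModel]:
        return [self.transcripts[t] for t in self.genes.get(gene_id, [])]

    def gene_strand(self, gene_id: str) -> str:
        return self.gene_transcripts(gene_id)[0].strand

    def gene_span(self, gene_id: str) -> tuple[str, int, int]:
        txs = self.gene_transcripts(gene_id)
        return txs[0].chrom, min(t.start for t in txs), max(t.end for t in txs)

    def gene_junctions(self, gene_id: str) -> set[Interval]:
        out: set[Interval] = set()
        for t in self.gene_transcripts(gene_id):
            out.update(t.junctions)
        return out

    def gene_splice_sites(self, gene_id: str) -> tuple[set[int], set[int]]:
        """(donor-side ends, acceptor-side starts) over all isoforms, in
        genomic coordinates (left/right intron boundaries, strand-agnostic)."""
        lefts, rights = set(), set()
        for s, e in self.gene_junctions(gene_id):
            lefts.add(s)
            rights.add(e)
        return lefts, rights

    def exons_of_gene(self, gene_id: str) -> set[Interval]:
        out: set[Interval] = set()
        for t in self.gene_transcripts(gene_id):
            out.update(t.exons)
        return out

    def all_known_exons(self) -> dict[str, list[Interval]]:
        by_chrom: dict[str, set[Interval]] = {}
        for t in self:
            by_chrom.setdefault(t.chrom, set()).update(t.exons)
        return {c: sorted(v) for c, v in by_chrom.items()}

    def genes_overlapping(self, chrom: str, start: int, end: int) -> list[str]:
        out = []
        for g in self.genes:
            c, gs, ge = self.gene_span(g)
            if c == chrom and gs < end and start < ge:
                out.append(g)
        return sorted(out)


# --- demultiplexing -------------------------------------------------------

STATUS_ASSIGNED = "assigned"
STATUS_AMBIGUOUS = "ambiguous"
STATUS_NO_TAIL = "no_tail"
STATUS_NO_MATCH = "no_match"
STATUS_MALFORMED = "malformed"

DEMUX_STATUSES = (
    STATUS_ASSIGNED,
    STATUS_AMBIGUOUS,
    STATUS_NO_TAIL,
    STATUS_NO_MATCH,
    STATUS_MALFORMED,
)


@dataclass(frozen=True)
class DemuxRecord:
    read_id: str
    status: str
    barcode: Optional[str] = None
    umi: Optional[str] = None
    orientation: Optional[str] = None  # 'sense' | 'antisense'
    hamming: Optional[int] = None

    def __post_init__(self) -> None:
        if self.status not in DEMUX_STATUSES:
            raise ValueError(f"bad status {self.status!r}")
        present = all(v is not None for v in (self.barcode, self.umi, self.orientation, self.hamming))
        if (self.status == STATUS_ASSIGNED) != present:
            raise ValueError("assigned status must carry barcode/umi/orientation/hamming, and only then")


# --- alignment ------------------------------------------------------------


@dataclass(frozen=True)
class Insertion:
    query_pos: int  # query offset (cDNA-sense) where inserted bases start
    length: int
    target_pos: int  # target coordinate of the insertion point


@dataclass
class SplicedAlignment:
    read_id: str
    target_kind: str  # 'transcriptome' | 'genome'
    target_id: str  # transcript id or chromosome
    is_reverse: bool
    blocks: list[Interval]  # target-space aligned blocks, increasing
    gap_is_splice: list[bool]  # one flag per inter-block gap
    insertions: list[Insertion]
    nm: int  # mismatching/edited columns
    query_length: int
    aligned_query_bases: int

    def __post_init__(self) -> None:
        if len(self.gap_is_splice) != max(len(self.blocks) - 1, 0):
            raise ValueError("gap flags must match number of inter-block gaps")
        for (s1, e1), (s2, e2) in zip(self.blocks, self.blocks[1:]):
            if not (s1 < e1 <= s2 < e2):
                raise ValueError(f"blocks not strictly increasing: {self.blocks}")

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]

    @property
    def aligned_target_bases(self) -> int:
        return sum(e - s for s, e in self.blocks)

    @property
    def identity(self) -> float:
        cols = self.aligned_target_bases + sum(i.length for i in self.insertions)
        return max(0.0, 1.0 - self.nm / cols) if cols else 0.0

    @property
    def coverage(self) -> float:
        return self.aligned_query_bases / self.query_length if self.query_length else 0.0

    @property
    def junctions(self) -> tuple[Interval, ...]:
        return tuple(
            (a[1], b[0])
            for (a, b), is_splice in zip(zip(self.blocks, self.blocks[1:]), self.gap_is_splice)
            if is_splice
        )


@dataclass(frozen=True)
class IsoformAssignment:
    read_id: str
    barcode: Optional[str]
    umi: Optional[str]
    category: str
    transcript_id: Optional[str] = None
    gene_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"bad category {self.category!r}")
        needs_tx = self.category in (FULL_SPLICE_MATCH, INCOMPLETE_SPLICE_MATCH)
        if needs_tx != (self.transcript_id is not None):
            raise ValueError("transcript id present iff category is a splice match")


# --- novelty --------------------------------------------------------------


@dataclass(frozen=True)
class NovelExonCall:
    chrom: str
    start: int
    end: int
    gene_id: str
    intron: Interval
    read_ids: frozenset[str]

    @property
    def n_support(self) -> int:
        return len(self.read_ids)

    @property
    def frame_preserving(self) -> bool:
        return (self.end - self.start) % 3 == 0


@dataclass
class NovelTranscript:
    model: TranscriptModel
    event: str
    support: dict[str, int]  # sample -> read count
    provenance: str  # closest annotated transcript id
    coding: Optional[bool] = None  # None = unknown
    read_ids: tuple[str, ...] = field(default_factory=tuple)

    @property
    def total_support(self) -> int:
        return sum(self.support.values())


# --- immunoglobulin -------------------------------------------------------


@dataclass(frozen=True)
class SegmentHit:
    segment_id: str
    segment_class: str  # 'V' | 'J' | 'C'
    read_span: Interval  # cDNA-sense coordinates on the read
    matched_length: int
    identity: float


@dataclass(frozen=True)
class VJCall:
    read_id: str
    v: SegmentHit
    j: SegmentHit

    @property
    def junction_pos(self) -> int:
        return self.v.read_span[1]

    @property
    def ordered(self) -> bool:
        """V upstream of J on the cDNA sense strand (small end overlaps
        from alignment jitter at the recombination junction tolerated)."""
        return (
            self.v.read_span[0] < self.j.read_span[0]
            and self.v.read_span[1] <= self.j.read_span[1]
        )
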