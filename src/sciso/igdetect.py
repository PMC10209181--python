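"""Detection of VJ-recombined immunoglobulin transcripts in long reads.

V and J (and optionally constant) segment sequences are indexed by exact
k-mers; reads with a seed for a segment are then aligned against that
full segment with infix (free-end-gap) edit-distance alignment via edlib,
on both strands. A hit must reach the per-class minimum matched length
(V >= ``min_v_len``, J >= ``min_j_len``) and a local identity floor. A
read is called VJ-recombined when its best V hit ends before its best J
hit starts on the cDNA sense strand - the layout produced by V-to-J
somatic recombination followed by splicing to the constant exon.

An exhaustive scanner (no seeding) is kept alongside as the oracle for
the seeded path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import edlib

from .config import DEFAULT_CONFIG, PipelineConfig
from .models import DemuxRecord, SegmentHit, VJCall
from .sequence import revcomp


class SegmentError(ValueError):
    """Raised for malformed segment inputs (e.g. duplicate ids)."""


@dataclass(frozen=True)
class Segment:
    segment_id: str
    segment_class: str  # 'V' | 'J' | 'C'
    seq: str


class SegmentIndex:
    """Exact k-mer index over immunoglobulin segments.

    Short segments (below ``full_scan_max_len``, e.g. J segments of a few
    dozen nt) are kept on a fallback list that is aligned against every
    read: a handful of sequencing errors can destroy every exact k-mer of
    a short segment, so seeding them would cost sensitivity for a
    negligible saving.
    """

    def __init__(
        self,
        segments: Sequence[Segment],
        k: int = DEFAULT_CONFIG.ig_seed_k,
        full_scan_max_len: int = 50,
    ):
        ids = [s.segment_id for s in segments]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise SegmentError(f"duplicate segment ids: {dupes}")
        self.k = k
        self.segments = {s.segment_id: s for s in segments}
        self.kmers: dict[str, list[tuple[str, int]]] = {}
        self.unseedable: list[str] = []
        for s in segments:
            if len(s.seq) < max(k, full_scan_max_len):
                self.unseedable.append(s.segment_id)
            for off in range(len(s.seq) - k + 1):
                self.kmers.setdefault(s.seq[off : off + k], []).append((s.segment_id, off))

    def seeded_segments(self, seq: str) -> set[str]:
        found: set[str] = set()
        for off in range(len(seq) - self.k + 1):
            for seg_id, _ in self.kmers.get(seq[off : off + self.k], ()):
                found.add(seg_id)
        return found


def build_segment_index(
    v_segments: Mapping[str, str],
    j_segments: Mapping[str, str],
    c_segments: Optional[Mapping[str, str]] = None,
    k: int = DEFAULT_CONFIG.ig_seed_k,
) -> SegmentIndex:
    segs = [Segment(i, "V", s.upper()) for i, s in v_segments.items()]
    segs += [Segment(i, "J", s.upper()) for i, s in j_segments.items()]
    if c_segments:
        segs += [Segment(i, "C", s.upper()) for i, s in c_segments.items()]
    return SegmentIndex(segs, k=k)


def _min_len_for(segment_class: str, config: PipelineConfig) -> int:
    if segment_class == "V":
        return config.min_v_len
    if segment_class == "J":
        return config.min_j_len
    return 1


def _align_segment(seg: Segment, seq: str) -> Optional[tuple[int, int, float, int]]:
    """Infix-align a segment into a read; returns (start, end, identity,
    matched_length) of the best location, or None when nothing aligns."""
    res = edlib.align(seg.seq, seq, mode="HW", task="locations")
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    start, end = res["locations"][0]
    end += 1
    identity = 1.0 - res["editDistance"] / len(seg.seq)
    return start, end, identity, end - start


def _scan_oriented(
    seq: str, index: SegmentIndex, candidates: Iterable[str], config: PipelineConfig
) -> list[SegmentHit]:
    hits = []
    for seg_id in sorted(candidates):
        seg = index.segments[seg_id]
        res = _align_segment(seg, seq)
        if res is None:
            continue
        start, end, identity, matched = res
        if identity < config.ig_min_identity:
            continue
        if matched < _min_len_for(seg.segment_class, config):
            continue
        hits.append(SegmentHit(seg_id, seg.segment_class, (start, end), matched, identity))
    return hits


def scan_read(
    seq: str,
    index: SegmentIndex,
    config: PipelineConfig = DEFAULT_CONFIG,
    exhaustive: bool = False,
) -> list[SegmentHit]:
    """Per-segment hits on a read, in cDNA-sense coordinates.

    Both strands are scanned; the orientation with the larger total
    matched length is taken as cDNA sense and hits are reported in its
    coordinates. With ``exhaustive=True`` the k-mer seeding is bypassed
    and every segment is aligned (the oracle path).
    """
    seq = seq.upper()
    rc = revcomp(seq)
    per_strand = []
    for oriented in (seq, rc):
        if exhaustive:
            candidates: Iterable[str] = index.segments
        else:
            candidates = index.seeded_segments(oriented) | set(index.unseedable)
        per_strand.append(_scan_oriented(oriented, index, candidates, config))
    fw, rv = per_strand
    score_fw = sum(h.matched_length for h in fw)
    score_rv = sum(h.matched_length for h in rv)
    return fw if score_fw >= score_rv else rv


def _best_hit(hits: Sequence[SegmentHit], segment_class: str) -> Optional[SegmentHit]:
    pool = [h for h in hits if h.segment_class == segment_class]
    if not pool:
        return None
    return min(pool, key=lambda h: (-h.matched_length, -h.identity, h.segment_id))


def call_vj(
    read_id: str,
    hits: Sequence[SegmentHit],
    max_overlap: int = DEFAULT_CONFIG.microindel_max,
) -> Optional[VJCall]:
    """Emit a VJ call iff the best V hit lies upstream of the best J hit
    on the cDNA sense strand.

    The recombined V end abuts the J start, so alignment jitter of a few
    bases at the junction can make the best hits overlap slightly;
    overlaps up to ``max_overlap`` nt are tolerated.
    """
    v = _best_hit(hits, "V")
    j = _best_hit(hits, "J")
    if v is None or j is None:
        return None
    call = VJCall(read_id=read_id, v=v, j=j)
    if not call.ordered or v.read_span[1] - j.read_span[0] > max_overlap:
        return None
    return call


def detect_vj(
    reads: Iterable[tuple[str, str]],
    index: SegmentIndex,
    config: PipelineConfig = DEFAULT_CONFIG,
    exhaustive: bool = False,
) -> tuple[list[VJCall], dict[str, list[SegmentHit]]]:
    """Scan reads and call VJ recombination; returns (calls, hits per read)."""
    calls: list[VJCall] = []
    all_hits: dict[str, list[SegmentHit]] = {}
    for read_id, seq in reads:
        hits = scan_read(seq, index, config, exhaustive=exhaustive)
        if hits:
            all_hits[read_id] = hits
        call = call_vj(read_id, hits)
        if call is not None:
            calls.append(call)
    return calls, all_hits


def presence_matrix(
    calls: Sequence[VJCall],
    hits: Mapping[str, Sequence[SegmentHit]],
    segments: Sequence[str],
    demux_records: Optional[Mapping[str, DemuxRecord]] = None,
    cluster_of_barcode: Optional[Mapping[str, str]] = None,
) -> tuple["pd.DataFrame", "pd.Series"]:
    """Binary reads x segments presence table for called reads, plus
    per-cluster counts of called, demux-assigned reads."""
    import pandas as pd

    called_ids = [c.read_id for c in calls]
    mat = pd.DataFrame(0, index=pd.Index(called_ids, name="read_id"), columns=list(segments), dtype=int)
    for rid in called_ids:
        for h in hits.get(rid, ()):
            if h.segment_id in mat.columns:
                mat.loc[rid, h.segment_id] = 1

    counts: dict[str, int] = {}
    if demux_records and cluster_of_barcode:
        for rid in called_ids:
            rec = demux_records.get(rid)
            if rec is not None and rec.barcode is not None:
                cl = cluster_of_barcode.get(rec.barcode)
                if cl is not None:
                    counts[cl] = counts.get(cl, 0) + 1
    return mat, pd.Series(counts, dtype=int).sort_index()
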