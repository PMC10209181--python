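"""Cell-barcode demultiplexing of full-length cDNA long reads.

A sense-oriented read carries ``[barcode][UMI][polyT][rev-comp cDNA]``.
Orientation is decided by locating the polyT tail (or its polyA mirror on
the antisense strand) immediately downstream of the putative barcode/UMI
prefix; the barcode is then extracted positionally and corrected against
the short-read whitelist by Hamming distance (up to ``max_hamming``
mismatches over the 16-mer, ties declared ambiguous and dropped). The UMI
is taken verbatim. Assigned reads are re-oriented to cDNA sense with the
barcode/UMI/tail prefix clipped off.

Two barcode matchers are provided: a vectorised NumPy matcher used in
production and a plain exhaustive scan kept as its oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pysam

from .config import DEFAULT_CONFIG, ConfigError, PipelineConfig
from .models import (
    DemuxRecord,
    STATUS_AMBIGUOUS,
    STATUS_ASSIGNED,
    STATUS_MALFORMED,
    STATUS_NO_MATCH,
    STATUS_NO_TAIL,
)
from .sequence import revcomp

ReadLike = Tuple[str, str]

_TAIL_SEARCH_SLACK = 8  # tail may start up to this many bases past the BC/UMI prefix
_TAIL_SCAN_CAP = 150  # longest tail extension considered

_VALID = set("ACGTN")


@dataclass(frozen=True)
class TailHit:
    orientation: str  # 'sense' | 'antisense'
    start: int  # tail start on the oriented (sense-layout) read
    end: int  # tail end (exclusive) on the oriented read
    mismatches: int

    @property
    def length(self) -> int:
        return self.end - self.start


def _scan_polyt(seq: str, cfg: PipelineConfig) -> Optional[tuple[int, int, int]]:
    """Find a polyT run starting within the allowed window; returns
    (start, end, mismatches) of the earliest qualifying tail, else None."""
    lo = cfg.prefix_length
    hi = min(lo + _TAIL_SEARCH_SLACK, max(len(seq) - cfg.min_tail_len, -1))
    for s in range(lo, hi + 1):
        window = seq[s : s + _TAIL_SCAN_CAP]
        non_t = np.cumsum(np.frombuffer(window.encode(), dtype=np.uint8) != ord("T"))
        ks = np.arange(1, len(window) + 1)
        ok = (non_t <= np.floor(ks * cfg.tail_max_mismatch_frac).astype(int)) & (ks >= cfg.min_tail_len)
        if not ok.any():
            continue
        # the tail end is found greedily: run through T's, stepping over an
        # isolated mismatch only when two T's follow it (so the scan stops
        # at the tail/cDNA boundary instead of creeping into the insert)
        end, cap = s, min(len(seq), s + _TAIL_SCAN_CAP)
        mismatches = 0
        while end < cap:
            if seq[end] == "T":
                end += 1
            elif seq[end + 1 : end + 3] == "TT":
                mismatches += 1
                end += 1
            else:
                break
        while end > s and seq[end - 1] != "T":
            end -= 1
        return s, end, mismatches
    return None


def locate_tail(seq: str, config: PipelineConfig = DEFAULT_CONFIG) -> Optional[TailHit]:
    """Locate the polyT (sense) or polyA (antisense) tail of a read.

    Returns the best hit over both orientations, or None when the read is
    too short or neither orientation shows a qualifying tail.
    """
    if len(seq) < config.prefix_length + config.min_tail_len:
        return None
    hits = []
    for orientation, oriented in (("sense", seq), ("antisense", revcomp(seq))):
        found = _scan_polyt(oriented, config)
        if found is not None:
            s, e, mm = found
            hits.append(TailHit(orientation, s, e, mm))
    if not hits:
        return None
    if len(hits) == 1:
        return hits[0]
    # symmetric tie-break: longer tail, then cleaner, then lexicographic prefix
    def key(h: TailHit):
        oriented = seq if h.orientation == "sense" else revcomp(seq)
        return (-h.length, h.mismatches, oriented[: config.prefix_length])

    return min(hits, key=key)


# --------------------------------------------------------------------------
# barcode matching

MATCH_ASSIGNED = STATUS_ASSIGNED
MATCH_AMBIGUOUS = STATUS_AMBIGUOUS
MATCH_NO_MATCH = STATUS_NO_MATCH

_ENCODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def match_barcode_scan(
    raw: str, whitelist: Sequence[str], max_hamming: int
) -> tuple[str, Optional[str], Optional[int]]:
    """Exhaustive Hamming scan over the whitelist (the reference oracle).

    'N' in the raw barcode mismatches every base. Returns
    (status, corrected barcode or None, distance or None).
    """
    if not whitelist:
        raise ConfigError("empty whitelist")
    best_d, best_bc, ties = None, None, 0
    for wl in whitelist:
        d = sum(1 for a, b in zip(raw, wl) if a != b or a == "N")
        if best_d is None or d < best_d:
            best_d, best_bc, ties = d, wl, 1
        elif d == best_d:
            ties += 1
    if best_d is None or best_d > max_hamming:
        return MATCH_NO_MATCH, None, None
    if ties > 1:
        return MATCH_AMBIGUOUS, None, None
    return MATCH_ASSIGNED, best_bc, best_d


class BarcodeMatcher:
    """Vectorised Hamming matcher over a fixed whitelist."""

    def __init__(self, whitelist: Sequence[str], config: PipelineConfig = DEFAULT_CONFIG):
        if not whitelist:
            raise ConfigError("empty whitelist")
        lens = {len(b) for b in whitelist}
        if lens != {config.barcode_length}:
            raise ConfigError(f"whitelist barcodes must all be {config.barcode_length} nt, got lengths {sorted(lens)}")
        if len(set(whitelist)) != len(whitelist):
            raise ConfigError("whitelist barcodes must be unique")
        self.whitelist = list(whitelist)
        self.config = config
        self._wl = np.array(
            [[_ENCODE[b] for b in bc] for bc in self.whitelist], dtype=np.uint8
        )

    def match(self, raw: str, max_hamming: Optional[int] = None) -> tuple[str, Optional[str], Optional[int]]:
        if max_hamming is None:
            max_hamming = self.config.max_hamming
        q = np.array([_ENCODE.get(b, 4) for b in raw], dtype=np.uint8)
        mism = (self._wl != q[None, :]) | (q[None, :] == 4)
        dists = mism.sum(axis=1)
        best = int(dists.min())
        if best > max_hamming:
            return MATCH_NO_MATCH, None, None
        idx = np.flatnonzero(dists == best)
        if idx.size > 1:
            return MATCH_AMBIGUOUS, None, None
        return MATCH_ASSIGNED, self.whitelist[int(idx[0])], best


# --------------------------------------------------------------------------
# whole-read demultiplexing


@dataclass(frozen=True)
class AssignedRead:
    read_id: str
    barcode: str
    umi: str
    seq: str  # cDNA, re-oriented to sense


@dataclass
class DemuxResult:
    records: list[DemuxRecord]
    assigned: list[AssignedRead]
    summary: dict

    def records_by_id(self) -> dict[str, DemuxRecord]:
        return {r.read_id: r for r in self.records}


def iter_fastq(path: Union[str, Path]) -> Iterator[ReadLike]:
    with pysam.FastxFile(str(path)) as fh:
        for entry in fh:
            yield entry.name, (entry.sequence or "")


def load_whitelist(path: Union[str, Path]) -> dict[str, dict[str, str]]:
    """Read a whitelist TSV: barcode, cluster and optional sample/condition."""
    out: dict[str, dict[str, str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if not parts or not parts[0]:
                continue
            bc = parts[0]
            if bc in out:
                raise ConfigError(f"duplicate whitelist barcode {bc}")
            out[bc] = {
                "cluster": parts[1] if len(parts) > 1 else "cluster1",
                "sample": parts[2] if len(parts) > 2 else "S1",
                "condition": parts[3] if len(parts) > 3 else "unknown",
            }
    if not out:
        raise ConfigError(f"empty whitelist: {path}")
    return out


def demultiplex(
    reads: Union[str, Path, Iterable[ReadLike]],
    whitelist: Union[Sequence[str], Mapping[str, object]],
    config: PipelineConfig = DEFAULT_CONFIG,
    max_hamming: Optional[int] = None,
) -> DemuxResult:
    """Assign every read to a whitelist barcode (or a failure status).

    Emits exactly one :class:`DemuxRecord` per input read. Assigned reads
    are returned clipped of barcode/UMI/tail and re-oriented to cDNA sense.
    """
    if isinstance(reads, (str, Path)):
        reads = iter_fastq(reads)
    matcher = BarcodeMatcher(list(whitelist), config)
    records: list[DemuxRecord] = []
    assigned: list[AssignedRead] = []
    counts = {s: 0 for s in (STATUS_ASSIGNED, STATUS_AMBIGUOUS, STATUS_NO_TAIL, STATUS_NO_MATCH, STATUS_MALFORMED)}

    for read_id, seq in reads:
        seq = (seq or "").upper()
        if not seq or not set(seq) <= _VALID:
            records.append(DemuxRecord(read_id, STATUS_MALFORMED))
            counts[STATUS_MALFORMED] += 1
            continue
        hit = locate_tail(seq, config)
        if hit is None:
            records.append(DemuxRecord(read_id, STATUS_NO_TAIL))
            counts[STATUS_NO_TAIL] += 1
            continue
        oriented = seq if hit.orientation == "sense" else revcomp(seq)
        raw_bc = oriented[: config.barcode_length]
        umi = oriented[config.barcode_length : config.prefix_length]
        status, bc, dist = matcher.match(raw_bc, max_hamming)
        if status != MATCH_ASSIGNED:
            records.append(DemuxRecord(read_id, status))
            counts[status] += 1
            continue
        records.append(
            DemuxRecord(read_id, STATUS_ASSIGNED, barcode=bc, umi=umi, orientation=hit.orientation, hamming=dist)
        )
        counts[STATUS_ASSIGNED] += 1
        assigned.append(AssignedRead(read_id, bc, umi, revcomp(oriented[hit.end :])))

    n_reads = len(records)
    summary = {
        "n_reads": n_reads,
        "n_assigned": counts[STATUS_ASSIGNED],
        "fraction_assigned": counts[STATUS_ASSIGNED] / n_reads if n_reads else None,
        "per_status": counts,
    }
    return DemuxResult(records=records, assigned=assigned, summary=summary)


# --------------------------------------------------------------------------
# file output


def write_demux_fastq(result: DemuxResult, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for r in result.assigned:
            fh.write(f"@{r.read_id} CB:Z:{r.barcode} UB:Z:{r.umi}\n{r.seq}\n+\n{'I' * len(r.seq)}\n")


def write_demux_tsv(result: DemuxResult, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tstatus\tbarcode\tumi\torientation\thamming\n")
        for r in result.records:
            fh.write(
                f"{r.read_id}\t{r.status}\t{r.barcode or ''}\t{r.umi or ''}\t"
                f"{r.orientation or ''}\t{'' if r.hamming is None else r.hamming}\n"
            )


def read_demux_tsv(path: Union[str, Path]) -> list[DemuxRecord]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            rid, status, bc, umi, ori, ham = line.rstrip("\n").split("\t")
            out.append(
                DemuxRecord(
                    rid,
                    status,
                    barcode=bc or None,
                    umi=umi or None,
                    orientation=ori or None,
                    hamming=int(ham) if ham else None,
                )
            )
    return out
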