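"""Isoform-level quantification from spliced long-read alignments.

The identity criterion for a read is its ordered splice-junction chain in
genome space: a read is a *full splice match* (FSM) when its chain equals
an annotated transcript's complete chain, an *incomplete splice match*
(ISM) when it is a contiguous sub-chain (the typical 5'-truncated read of
an oligo-dT library), a *novel combination* when all junctions are known
but the chain matches no transcript, and a *novel junction* read when at
least one junction is unannotated. Alignments must pass identity and
query-coverage floors before classification, and junctions within the
microindel tolerance of an annotated junction are snapped onto it first.

Reads are collapsed to molecules by (cell barcode, gene, UMI), and
molecules are tabulated into a sparse cells x transcripts matrix
(:class:`anndata.AnnData`) keyed by the short-read cluster labels.
"""

from __future__ import annotations

import logging
from bisect import bisect_left
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import anndata as ad
import numpy as np
import pandas as pd
import pysam
import scipy.sparse as sp

from .config import DEFAULT_CONFIG, PipelineConfig
from .models import (
    ANTISENSE,
    FULL_SPLICE_MATCH,
    INCOMPLETE_SPLICE_MATCH,
    INTERGENIC,
    NOVEL_COMBINATION,
    NOVEL_JUNCTION,
    UNASSIGNED,
    Annotation,
    DemuxRecord,
    Insertion,
    Interval,
    IsoformAssignment,
    SplicedAlignment,
)

logger = logging.getLogger(__name__)

BIOTYPE_GROUPS = ("protein_coding", "lncRNA", "retained_intron", "pseudogene", "other")

_QUERY_CONSUMING = {0, 1, 4, 7, 8}  # M I S = X
_REF_CONSUMING = {0, 2, 3, 7, 8}  # M D N = X


# --------------------------------------------------------------------------
# SAM parsing


def _alignment_from_record(rec: "pysam.AlignedSegment", target_kind: str) -> SplicedAlignment:
    blocks: list[Interval] = []
    gap_is_splice: list[bool] = []
    insertions: list[Insertion] = []
    ref = rec.reference_start
    q = 0
    cur_start: Optional[int] = None
    n_mismatch_ops = 0
    for op, ln in rec.cigartuples:
        if op in (0, 7, 8):  # M = X
            if cur_start is None:
                cur_start = ref
            if op == 8:
                n_mismatch_ops += ln
            ref += ln
            q += ln
        elif op == 1:  # I
            insertions.append(Insertion(query_pos=q, length=ln, target_pos=ref))
            n_mismatch_ops += ln
            q += ln
        elif op in (2, 3):  # D N
            if cur_start is not None:
                blocks.append((cur_start, ref))
                cur_start = None
                gap_is_splice.append(op == 3)
            ref += ln
            if op == 2:
                n_mismatch_ops += ln
        elif op == 4:  # S
            q += ln
        # H/P consume nothing we track
    if cur_start is not None:
        blocks.append((cur_start, ref))
    else:  # trailing D/N; drop the dangling gap flag
        gap_is_splice = gap_is_splice[: max(len(blocks) - 1, 0)]

    nm = rec.get_tag("NM") if rec.has_tag("NM") else n_mismatch_ops
    qlen = rec.infer_read_length() or q
    aligned_q = sum(ln for op, ln in rec.cigartuples if op in (0, 1, 7, 8))
    return SplicedAlignment(
        read_id=rec.query_name,
        target_kind=target_kind,
        target_id=rec.reference_name,
        is_reverse=rec.is_reverse,
        blocks=blocks,
        gap_is_splice=gap_is_splice,
        insertions=insertions,
        nm=int(nm),
        query_length=qlen,
        aligned_query_bases=aligned_q,
    )


def parse_alignments(
    sam: Union[str, Path, Iterable["pysam.AlignedSegment"]],
    target_kind: str,
) -> tuple[list[SplicedAlignment], dict[str, int]]:
    """Parse primary alignments of a SAM stream into spliced alignments.

    Secondary/supplementary records and unmapped reads are skipped and
    counted; records whose CIGAR disagrees with their sequence length are
    rejected with a warning.
    """
    if target_kind not in ("genome", "transcriptome"):
        raise ValueError(f"bad target kind {target_kind!r}")
    out: list[SplicedAlignment] = []
    counts = {"primary": 0, "unmapped": 0, "secondary": 0, "rejected": 0}
    if isinstance(sam, (str, Path)):
        records = _iter_sam_records(sam, counts)
    else:
        records = sam
    for rec in records:
        if rec.is_unmapped:
            counts["unmapped"] += 1
            continue
        if rec.is_secondary or rec.is_supplementary:
            counts["secondary"] += 1
            continue
        if rec.query_sequence is not None and rec.cigartuples is not None:
            q_consumed = sum(ln for op, ln in rec.cigartuples if op in _QUERY_CONSUMING)
            if q_consumed != len(rec.query_sequence):
                counts["rejected"] += 1
                logger.warning(
                    "read %s: CIGAR consumes %d query bases but sequence has %d; record rejected",
                    rec.query_name, q_consumed, len(rec.query_sequence),
                )
                continue
        out.append(_alignment_from_record(rec, target_kind))
        counts["primary"] += 1
    return out, counts


def _iter_sam_records(path: Union[str, Path], counts: dict[str, int]):
    """Line-wise SAM reader with per-record error handling (htslib's file
    reader aborts the whole stream at the first malformed record)."""
    header_lines: list[str] = []
    with open(path) as fh:
        body_start = 0
        for line in fh:
            if line.startswith("@"):
                header_lines.append(line)
                body_start += 1
            else:
                break
    header = pysam.AlignmentHeader.from_text("".join(header_lines))
    with open(path) as fh:
        for i, line in enumerate(fh):
            if line.startswith("@") or not line.strip():
                continue
            try:
                yield pysam.AlignedSegment.fromstring(line.rstrip("\n"), header)
            except ValueError as exc:
                counts["rejected"] += 1
                logger.warning("SAM line %d rejected: %s", i + 1, exc)


# --------------------------------------------------------------------------
# junction snapping


class JunctionIndex:
    """Annotated junctions per chromosome, sorted for nearest lookup."""

    def __init__(self, annotation: Annotation):
        per_chrom: dict[str, set[Interval]] = {}
        for t in annotation:
            per_chrom.setdefault(t.chrom, set()).update(t.junctions)
        self._sorted = {c: sorted(v) for c, v in per_chrom.items()}

    def nearest(self, chrom: str, junction: Interval, tolerance: int) -> Optional[Interval]:
        """Annotated junction with both ends within ``tolerance``, nearest
        by total shift; None when no junction qualifies."""
        juncs = self._sorted.get(chrom, [])
        if not juncs:
            return None
        i = bisect_left(juncs, (junction[0] - tolerance, -1))
        best, best_cost = None, None
        while i < len(juncs) and juncs[i][0] <= junction[0] + tolerance:
            ds = abs(juncs[i][0] - junction[0])
            de = abs(juncs[i][1] - junction[1])
            if de <= tolerance:
                cost = ds + de
                if best_cost is None or cost < best_cost or (cost == best_cost and juncs[i] < best):
                    best, best_cost = juncs[i], cost
            i += 1
        return best


def snap_junctions(
    aln: SplicedAlignment,
    annotation: Union[Annotation, JunctionIndex],
    tolerance: int = DEFAULT_CONFIG.microindel_max,
) -> SplicedAlignment:
    """Absorb sub-tolerance indels and snap junctions onto annotated ones.

    Deletion gaps shorter than ``tolerance`` are merged into their
    flanking blocks; every remaining junction within ``tolerance`` (both
    ends) of an annotated junction is moved onto it. Idempotent.
    """
    if aln.target_kind != "genome":
        raise ValueError("junction snapping operates on genome-space alignments")
    index = annotation if isinstance(annotation, JunctionIndex) else JunctionIndex(annotation)

    # absorb microindel gaps
    blocks: list[Interval] = [aln.blocks[0]]
    flags: list[bool] = []
    for (s, e), is_splice in zip(aln.blocks[1:], aln.gap_is_splice):
        gap = s - blocks[-1][1]
        if gap < tolerance and not is_splice:
            blocks[-1] = (blocks[-1][0], e)
        else:
            blocks.append((s, e))
            flags.append(is_splice or gap >= tolerance)

    # snap junctions
    for i in range(len(blocks) - 1):
        junction = (blocks[i][1], blocks[i + 1][0])
        target = index.nearest(aln.target_id, junction, tolerance)
        if target is not None and target != junction:
            s, e = target
            if blocks[i][0] < s and e < blocks[i + 1][1]:
                blocks[i] = (blocks[i][0], s)
                blocks[i + 1] = (e, blocks[i + 1][1])

    insertions = [ins for ins in aln.insertions if ins.length >= tolerance]
    return replace(aln, blocks=blocks, gap_is_splice=flags, insertions=insertions)


# --------------------------------------------------------------------------
# read -> isoform assignment


def _is_contiguous_subchain(chain: tuple, full: tuple) -> bool:
    if not chain:
        return True
    n, m = len(chain), len(full)
    return any(full[i : i + n] == chain for i in range(m - n + 1))


def read_strand(orientation: Optional[str], is_reverse: bool) -> Optional[str]:
    """Genomic strand of the cDNA sense sequence, from the demux
    orientation and the SAM reverse flag."""
    if orientation == "sense":
        return "-" if not is_reverse else "+"
    if orientation == "antisense":
        return "+" if not is_reverse else "-"
    return None


def assign_read(
    alignments: Sequence[SplicedAlignment],
    annotation: Annotation,
    config: PipelineConfig = DEFAULT_CONFIG,
    demux: Optional[DemuxRecord] = None,
) -> IsoformAssignment:
    """Classify one read's genome alignments against the annotation."""
    if not alignments:
        raise ValueError("assign_read requires at least one alignment")
    read_id = alignments[0].read_id
    barcode = demux.barcode if demux else None
    umi = demux.umi if demux else None

    def result(category, transcript_id=None, gene_id=None):
        return IsoformAssignment(read_id, barcode, umi, category, transcript_id, gene_id)

    survivors = [
        a
        for a in alignments
        if a.target_kind == "genome"
        and a.identity >= config.min_identity
        and a.coverage >= config.min_coverage
    ]
    if not survivors:
        return result(UNASSIGNED)
    best_score = max(a.identity * a.coverage for a in survivors)
    top = [a for a in survivors if a.identity * a.coverage == best_score]
    loci = {(a.target_id, a.start // 1_000_000) for a in top}
    if len(top) > 1 and len(loci) > 1:
        return result(UNASSIGNED)
    aln = top[0]

    strand = read_strand(demux.orientation if demux else None, aln.is_reverse)
    genes = annotation.genes_overlapping(aln.target_id, aln.start, aln.end)
    if not genes:
        return result(INTERGENIC)
    same = [g for g in genes if strand is None or annotation.gene_strand(g) == strand]
    if not same:
        return result(ANTISENSE)

    chain = aln.junctions
    tol = config.microindel_max
    fsm: list[str] = []
    ism: list[tuple[int, int, str]] = []  # (-shared, n_tx_junctions, tx id)
    for g in same:
        for t in annotation.gene_transcripts(g):
            tj = t.junctions
            if chain == tj and aln.start >= t.start - tol and aln.end <= t.end + tol:
                fsm.append(t.transcript_id)
            elif (
                _is_contiguous_subchain(chain, tj)
                and aln.start >= t.start - tol
                and aln.end <= t.end + tol
            ):
                ism.append((-len(chain), len(tj), t.transcript_id))
    if fsm:
        tid = sorted(fsm)[0]
        return result(FULL_SPLICE_MATCH, tid, annotation[tid].gene_id)
    if ism:
        ism.sort()
        tid = ism[0][2]
        return result(INCOMPLETE_SPLICE_MATCH, tid, annotation[tid].gene_id)

    # novel structure: attribute to the same-strand gene sharing most junctions
    def shared(g):
        return len(set(chain) & annotation.gene_junctions(g))

    gene = sorted(same, key=lambda g: (-shared(g), g))[0]
    known = annotation.gene_junctions(gene)
    if chain and all(j in known for j in chain):
        return result(NOVEL_COMBINATION, gene_id=gene)
    return result(NOVEL_JUNCTION, gene_id=gene)


# --------------------------------------------------------------------------
# UMI deduplication and matrices

MOLECULE_COLUMNS = ["barcode", "gene_id", "umi", "transcript_id", "support"]


def dedup_umi(assignments: Iterable[IsoformAssignment]) -> pd.DataFrame:
    """Collapse splice-matched reads to molecules by (barcode, gene, UMI).

    Each group becomes one molecule whose transcript is the modal
    transcript of its reads (ties to the lexicographically smallest id);
    ``support`` is the number of collapsed reads.
    """
    rows = [
        (a.barcode, a.gene_id, a.umi, a.transcript_id)
        for a in assignments
        if a.transcript_id is not None and a.barcode is not None and a.umi is not None
    ]
    if not rows:
        return pd.DataFrame(columns=MOLECULE_COLUMNS)
    df = pd.DataFrame(rows, columns=["barcode", "gene_id", "umi", "transcript_id"])
    per_tx = (
        df.groupby(["barcode", "gene_id", "umi", "transcript_id"], sort=True)
        .size()
        .reset_index(name="n")
    )
    # modal transcript; lexicographic tie-break comes free from the sort order
    per_tx = per_tx.sort_values(
        ["barcode", "gene_id", "umi", "n", "transcript_id"],
        ascending=[True, True, True, False, True],
    )
    rep = per_tx.drop_duplicates(["barcode", "gene_id", "umi"], keep="first")
    support = (
        df.groupby(["barcode", "gene_id", "umi"], sort=True).size().rename("support").reset_index()
    )
    out = rep.drop(columns="n").merge(support, on=["barcode", "gene_id", "umi"])
    return out[MOLECULE_COLUMNS].reset_index(drop=True)


def build_matrix(
    molecules: pd.DataFrame,
    cluster_labels: Mapping[str, str],
    transcripts: Optional[Sequence[str]] = None,
    gene_of_transcript: Optional[Mapping[str, str]] = None,
) -> ad.AnnData:
    """Tabulate molecules into a sparse cells x transcripts AnnData.

    Every barcode in ``cluster_labels`` becomes a row, including cells
    with zero molecules; a molecule whose barcode has no cluster label is
    a contract violation and raises.
    """
    barcodes = list(cluster_labels)
    unlabelled = set(molecules["barcode"]) - set(barcodes) if len(molecules) else set()
    if unlabelled:
        raise ValueError(f"molecules carry barcodes without cluster labels: {sorted(unlabelled)[:5]}")
    gene_map = dict(gene_of_transcript or {})
    if len(molecules):
        gene_map.update(dict(zip(molecules["transcript_id"], molecules["gene_id"])))
    if transcripts is None:
        transcripts = sorted(gene_map)
    tx_index = {t: i for i, t in enumerate(transcripts)}
    bc_index = {b: i for i, b in enumerate(barcodes)}

    if len(molecules):
        rows = molecules["barcode"].map(bc_index).to_numpy()
        cols = molecules["transcript_id"].map(tx_index).to_numpy()
        data = np.ones(len(molecules), dtype=np.int32)
        x = sp.coo_matrix((data, (rows, cols)), shape=(len(barcodes), len(transcripts))).tocsr()
    else:
        x = sp.csr_matrix((len(barcodes), len(transcripts)), dtype=np.int32)

    obs = pd.DataFrame({"cluster": [cluster_labels[b] for b in barcodes]}, index=pd.Index(barcodes, name="barcode"))
    var = pd.DataFrame(
        {"gene_id": [gene_map.get(t, "") for t in transcripts]},
        index=pd.Index(list(transcripts), name="transcript_id"),
    )
    return ad.AnnData(X=x, obs=obs, var=var)


def write_matrix_10x(adata: ad.AnnData, outdir: Union[str, Path]) -> None:
    """Write the matrix as a 10x-style MTX triplet."""
    import scipy.io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(outdir / "matrix.mtx"), sp.coo_matrix(adata.X.T))
    adata.obs.reset_index().to_csv(outdir / "barcodes.tsv", sep="\t", header=False, index=False)
    adata.var.reset_index().to_csv(outdir / "features.tsv", sep="\t", header=False, index=False)


def cluster_profiles(adata: ad.AnnData) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cluster transcript totals and per-(cluster, gene) isoform
    frequencies; genes absent from a cluster contribute no rows."""
    counts = np.asarray(adata.X.todense()) if sp.issparse(adata.X) else np.asarray(adata.X)
    df = pd.DataFrame(counts, index=adata.obs.index, columns=adata.var.index)
    df["cluster"] = adata.obs["cluster"].to_numpy()
    totals = df.groupby("cluster", observed=True).sum()
    long = totals.stack().rename("count").reset_index()
    long.columns = ["cluster", "transcript_id", "count"]
    long["gene_id"] = long["transcript_id"].map(adata.var["gene_id"])
    long = long[long["count"] > 0].copy()
    denom = long.groupby(["cluster", "gene_id"], observed=True)["count"].transform("sum")
    long["freq"] = long["count"] / denom
    cluster_totals = totals.sum(axis=1).rename("total_molecules").reset_index()
    return cluster_totals, long.reset_index(drop=True)


def per_cell_summary(adata: ad.AnnData, molecules: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Per-cell read/molecule/distinct-transcript counts and medians over
    cells with at least one assigned read."""
    if len(molecules):
        g = molecules.groupby("barcode")
        per_cell = pd.DataFrame(
            {
                "n_reads": g["support"].sum(),
                "n_molecules": g.size(),
                "n_distinct_transcripts": g["transcript_id"].nunique(),
            }
        )
    else:
        per_cell = pd.DataFrame(columns=["n_reads", "n_molecules", "n_distinct_transcripts"])
    per_cell = per_cell.reindex(adata.obs.index, fill_value=0)
    covered = per_cell[per_cell["n_reads"] >= 1]
    medians = {
        f"median_{c}": (float(covered[c].median()) if len(covered) else None)
        for c in per_cell.columns
    }
    return per_cell, medians


def biotype_group(biotype: str) -> str:
    return biotype if biotype in BIOTYPE_GROUPS else "other"


def biotype_composition(
    molecules: pd.DataFrame,
    annotation: Annotation,
    condition_by_barcode: Mapping[str, str],
    compare: bool = True,
) -> tuple[pd.DataFrame, Optional[pd.DataFrame]]:
    """Fractions of molecules per biotype group within each condition,
    with a two-proportion z-test per biotype between two conditions."""
    df = molecules.copy()
    df["condition"] = df["barcode"].map(dict(condition_by_barcode))
    df["biotype"] = [
        biotype_group(annotation[t].biotype) for t in df["transcript_id"]
    ]
    tab = (
        df.groupby(["condition", "biotype"], observed=True).size().unstack(fill_value=0)
        if len(df)
        else pd.DataFrame()
    )
    for b in BIOTYPE_GROUPS:
        if b not in tab.columns:
            tab[b] = 0
    tab = tab[list(BIOTYPE_GROUPS)]
    totals = tab.sum(axis=1)
    fractions = tab.div(totals, axis=0)

    tests = None
    conditions = list(tab.index)
    if compare:
        if len(conditions) > 2:
            raise ValueError(
                f"two-proportion comparison needs exactly 2 conditions, got {len(conditions)}"
            )
        if len(conditions) == 2:
            from statsmodels.stats.proportion import proportions_ztest

            c1, c2 = conditions
            rows = []
            for b in BIOTYPE_GROUPS:
                k = np.array([tab.loc[c1, b], tab.loc[c2, b]])
                n = np.array([totals[c1], totals[c2]])
                if n.min() == 0 or k.sum() == 0 or (n - k).sum() == 0:
                    stat, p = np.nan, np.nan
                else:
                    stat, p = proportions_ztest(k, n)
                rows.append((b, float(k[0]), float(k[1]), float(stat), float(p)))
            tests = pd.DataFrame(rows, columns=["biotype", f"count_{c1}", f"count_{c2}", "z", "p"])
    return fractions, tests
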