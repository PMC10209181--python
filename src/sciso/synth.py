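"""Synthetic single-cell long-read data with known ground truth.

The generator emulates the structure of a 10x Chromium (3' v2) + PacBio
full-length cDNA experiment. Each molecule, on its sense strand, reads

    [16 nt cell barcode][10 nt UMI][30 nt polyT][reverse-complemented cDNA]

and is emitted on a uniformly random strand with i.i.d. substitution
errors. A toy genome and multi-isoform annotation provide the substrate:
every gene has 3-10 exons, and alternative isoforms are derived from the
primary one by exactly one labelled splicing event (cassette-exon skip,
alternative 5'/3' splice site, or intron retention). Cells belong to
clusters whose per-gene isoform mixtures are symmetric-Dirichlet draws,
and to samples (two conditions) that differ in the fraction of molecules
drawn from noncoding genes. Unannotated exons and VJ-recombined
immunoglobulin molecules can be planted with read-level truth, and
error-free truth alignments are emitted as SAM against both the genome
and the transcriptome (barcode/UMI/polyT portions soft-clipped).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pysam
from Bio import SeqIO

from .config import DEFAULT_CONFIG, PipelineConfig
from .models import (
    ALT_3SS,
    ALT_5SS,
    CASSETTE_EXON,
    INTRON_RETENTION,
    Annotation,
    Interval,
    TranscriptModel,
)
from .sequence import BASES, random_dna, revcomp

TAIL_LEN = 30
QUAL_CHAR = "I"

_STOP_CODONS = {"TAA", "TAG", "TGA"}


class CapacityError(RuntimeError):
    """Raised when a generation request cannot be satisfied by construction."""


class InputError(ValueError):
    """Raised when generator inputs are empty or out of range."""


# --------------------------------------------------------------------------
# truth containers


@dataclass(frozen=True)
class CellInfo:
    barcode: str
    cluster: str
    sample: str
    condition: str


@dataclass(frozen=True)
class PlantedExon:
    chrom: str
    start: int
    end: int
    gene_id: str
    transcript_id: str  # host isoform the support reads otherwise follow
    intron: Interval
    tx_junction_pos: int  # 5'->3' transcript coordinate of the insertion point

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class MoleculeRecord:
    mol_id: str
    barcode: str
    umi: str
    kind: str  # 'normal' | 'novel_exon' | 'ig'
    transcript_id: Optional[str] = None
    trunc_offset: int = 0  # bases removed from the cDNA 5' end
    novel_exon: Optional[PlantedExon] = None
    vj: Optional[tuple[str, str]] = None


@dataclass(frozen=True)
class SimRead:
    """One emitted read; sequence is in the FASTQ (sequencer) orientation."""

    read_id: str
    seq: str
    flipped: bool  # FASTQ sequence is the reverse complement of the sense layout
    molecule: MoleculeRecord
    error_positions: tuple[int, ...]  # molecule-sense coordinates
    cdna_len: int

    @property
    def sense_seq(self) -> str:
        return revcomp(self.seq) if self.flipped else self.seq


@dataclass
class SyntheticTruth:
    config: PipelineConfig
    annotation: Annotation
    genome: dict[str, str]
    isoform_events: dict[str, tuple[str, str]]  # tx -> (parent tx, event label)
    cells: dict[str, CellInfo] = field(default_factory=dict)
    cluster_mixtures: dict[str, dict[str, dict[str, float]]] = field(default_factory=dict)
    noncoding_expression: dict[str, float] = field(default_factory=dict)
    molecule_log: dict[str, MoleculeRecord] = field(default_factory=dict)
    planted_novel_exons: list[PlantedExon] = field(default_factory=list)
    planted_vj: dict[str, tuple[str, str]] = field(default_factory=dict)
    _tx_seq_cache: dict[str, str] = field(default_factory=dict, repr=False)

    def transcript_seq(self, transcript_id: str) -> str:
        if transcript_id not in self._tx_seq_cache:
            t = self.annotation[transcript_id]
            self._tx_seq_cache[transcript_id] = t.spliced_sequence(self.genome)
        return self._tx_seq_cache[transcript_id]

    @property
    def clusters(self) -> list[str]:
        return sorted({c.cluster for c in self.cells.values()})

    def gene_is_noncoding(self, gene_id: str) -> bool:
        primary = self.annotation[f"{gene_id}.t1"]
        return primary.biotype in ("lncRNA", "pseudogene")


# --------------------------------------------------------------------------
# annotation + genome


def _apply_event(
    exons: tuple[Interval, ...], strand: str, event: str, rng: np.random.Generator
) -> Optional[tuple[Interval, ...]]:
    ex = list(exons)
    n = len(ex)
    if event == CASSETTE_EXON:
        i = int(rng.integers(1, n - 1))
        return tuple(ex[:i] + ex[i + 1 :])
    if event == INTRON_RETENTION:
        j = int(rng.integers(0, n - 1))
        merged = (ex[j][0], ex[j + 1][1])
        return tuple(ex[:j] + [merged] + ex[j + 2 :])
    # splice-site shifts
    j = int(rng.integers(0, n - 1))
    delta = int(rng.integers(6, 31)) * (1 if rng.random() < 0.5 else -1)
    donor_is_left = strand == "+"
    move_left_exon_end = (event == ALT_5SS) == donor_is_left
    if move_left_exon_end:
        s, e = ex[j]
        new_e = e + delta
        if not (s + 50 <= new_e <= ex[j + 1][0] - 30):
            return None
        ex[j] = (s, new_e)
    else:
        s, e = ex[j + 1]
        new_s = s + delta
        if not (ex[j][1] + 30 <= new_s <= e - 50):
            return None
        ex[j + 1] = (new_s, e)
    return tuple(ex)


def _tx_genomic_positions(t: TranscriptModel) -> list[int]:
    """Genomic position of every transcript base, in 5'->3' transcript order."""
    out: list[int] = []
    for s, e in t.exons_in_tx_order():
        out.extend(range(s, e) if t.strand == "+" else range(e - 1, s - 1, -1))
    return out


def _random_codon(rng: np.random.Generator) -> str:
    while True:
        c = random_dna(rng, 3)
        if c not in _STOP_CODONS:
            return c


def generate_annotation(
    n_genes: int,
    max_isoforms_per_gene: int,
    seed: int,
    *,
    noncoding_fraction: float = 0.15,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> SyntheticTruth:
    """Build a toy genome and multi-isoform annotation with labelled events."""
    if n_genes < 1 or max_isoforms_per_gene < 1:
        raise InputError("n_genes and max_isoforms_per_gene must be >= 1")
    rng = np.random.default_rng(seed)
    chrom = "chr1"
    cursor = 1000
    transcripts: list[TranscriptModel] = []
    events: dict[str, tuple[str, str]] = {}
    cds_requests: list[tuple[str, int, int]] = []  # (tx, cds_tx_start, cds_tx_end)

    for gi in range(n_genes):
        gene_id = f"G{gi + 1:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_ex = int(rng.integers(3, 11))
        exon_lens = [int(x) for x in rng.integers(100, 301, n_ex)]
        intron_lens = [int(x) for x in rng.integers(100, 601, max(n_ex - 1, 0))]
        exons = []
        pos = cursor
        for i, L in enumerate(exon_lens):
            exons.append((pos, pos + L))
            pos += L
            if i < n_ex - 1:
                pos += intron_lens[i]
        cursor = pos + int(rng.integers(500, 2001))

        noncoding = rng.random() < noncoding_fraction
        biotype = ("lncRNA" if rng.random() < 0.8 else "pseudogene") if noncoding else "protein_coding"
        primary_id = f"{gene_id}.t1"
        tx_len = sum(exon_lens)

        cds_span: Optional[Interval] = None
        if not noncoding:
            utr5 = int(rng.integers(15, 61))
            utr3 = int(rng.integers(15, 61))
            cds_len = (tx_len - utr5 - utr3) // 3 * 3
            cds_requests.append((primary_id, utr5, utr5 + cds_len))

        primary = TranscriptModel(primary_id, gene_id, chrom, strand, tuple(exons), biotype=biotype)
        if cds_requests and cds_requests[-1][0] == primary_id:
            pos_map = _tx_genomic_positions(primary)
            a, b = cds_requests[-1][1], cds_requests[-1][2]
            g = [pos_map[a], pos_map[b - 1]]
            cds_span = (min(g), max(g) + 1)
            primary = TranscriptModel(
                primary_id, gene_id, chrom, strand, tuple(exons), biotype=biotype, cds=cds_span
            )
        transcripts.append(primary)

        n_iso = int(rng.integers(1, max_isoforms_per_gene + 1))
        chains = {primary.junctions}
        k, attempts = 1, 0
        while k < n_iso and attempts < 30 * n_iso:
            attempts += 1
            event = str(rng.choice([CASSETTE_EXON, ALT_5SS, ALT_3SS, INTRON_RETENTION]))
            new_exons = _apply_event(primary.exons, strand, event, rng)
            if new_exons is None:
                continue
            tid = f"{gene_id}.t{k + 1}"
            bt = biotype
            if event == INTRON_RETENTION and biotype == "protein_coding":
                bt = "retained_intron"
            cand = TranscriptModel(tid, gene_id, chrom, strand, new_exons, biotype=bt)
            if cand.junctions in chains:
                continue
            chains.add(cand.junctions)
            transcripts.append(cand)
            events[tid] = (primary_id, event)
            k += 1

    genome = bytearray(random_dna(rng, cursor + 1000).encode())
    # overwrite coding sequence so each primary CDS is a stop-free ORF ending in TAA
    tx_by_id = {t.transcript_id: t for t in transcripts}
    comp = str.maketrans("ACGT", "TGCA")
    for tid, a, b in cds_requests:
        t = tx_by_id[tid]
        pos_map = _tx_genomic_positions(t)
        n_codons = (b - a) // 3
        cds_seq = "".join(_random_codon(rng) for _ in range(n_codons - 1)) + "TAA"
        for i, base in enumerate(cds_seq):
            gpos = pos_map[a + i]
            genome[gpos] = ord(base if t.strand == "+" else base.translate(comp))

    return SyntheticTruth(
        config=config,
        annotation=Annotation(transcripts),
        genome={chrom: genome.decode()},
        isoform_events=events,
    )


# --------------------------------------------------------------------------
# cells


def generate_cells(
    truth: SyntheticTruth,
    n_cells: int,
    n_clusters: int,
    concentration: float,
    seed: int,
    *,
    n_samples: int = 4,
    noncoding_expression: Optional[Mapping[str, float]] = None,
) -> SyntheticTruth:
    """Draw well-separated cell barcodes, cluster/sample labels and
    per-cluster isoform mixtures (symmetric Dirichlet)."""
    if not (n_cells >= n_clusters >= 1):
        raise InputError("need n_cells >= n_clusters >= 1")
    if concentration <= 0:
        raise InputError("concentration must be positive")
    rng = np.random.default_rng(seed)
    cfg = truth.config
    min_dist = 2 * cfg.max_hamming + 1

    barcodes: list[str] = []
    for _ in range(n_cells):
        for _attempt in range(2000):
            cand = random_dna(rng, cfg.barcode_length)
            if all(sum(a != b for a, b in zip(cand, w)) >= min_dist for w in barcodes):
                barcodes.append(cand)
                break
        else:
            raise CapacityError(
                f"cannot place {n_cells} barcodes of length {cfg.barcode_length} "
                f"at pairwise Hamming distance >= {min_dist}"
            )

    clusters = [f"cluster{i + 1}" for i in range(n_clusters)]
    samples = [f"S{j + 1}" for j in range(n_samples)]
    conditions = {s: ("young" if j < n_samples / 2 else "aged") for j, s in enumerate(samples)}

    truth.cells = {}
    for i, bc in enumerate(barcodes):
        cl = clusters[i] if i < n_clusters else clusters[int(rng.integers(0, n_clusters))]
        sm = samples[int(rng.integers(0, n_samples))]
        truth.cells[bc] = CellInfo(barcode=bc, cluster=cl, sample=sm, condition=conditions[sm])

    truth.cluster_mixtures = {}
    for cl in clusters:
        per_gene: dict[str, dict[str, float]] = {}
        for gene_id in sorted(truth.annotation.genes):
            txs = sorted(t.transcript_id for t in truth.annotation.gene_transcripts(gene_id))
            probs = rng.dirichlet(np.full(len(txs), concentration))
            per_gene[gene_id] = dict(zip(txs, probs.tolist()))
        truth.cluster_mixtures[cl] = per_gene

    truth.noncoding_expression = dict(
        noncoding_expression if noncoding_expression is not None else {"young": 0.10, "aged": 0.20}
    )
    return truth


# --------------------------------------------------------------------------
# reads


def _emit_read(
    truth: SyntheticTruth,
    molecule: MoleculeRecord,
    cdna: str,
    rng: np.random.Generator,
    error_rate: float,
) -> SimRead:
    sense = molecule.barcode + molecule.umi + "T" * TAIL_LEN + revcomp(cdna)
    err_pos: list[int] = []
    if error_rate > 0:
        hits = np.flatnonzero(rng.random(len(sense)) < error_rate)
        if hits.size:
            chars = list(sense)
            for p in hits:
                p = int(p)
                alternatives = [b for b in BASES if b != chars[p]]
                chars[p] = alternatives[int(rng.integers(0, 3))]
                err_pos.append(p)
            sense = "".join(chars)
    flipped = bool(rng.random() < 0.5)
    seq = revcomp(sense) if flipped else sense
    truth.molecule_log[molecule.mol_id] = molecule
    return SimRead(
        read_id=molecule.mol_id,
        seq=seq,
        flipped=flipped,
        molecule=molecule,
        error_positions=tuple(err_pos),
        cdna_len=len(cdna),
    )


def simulate_long_reads(
    truth: SyntheticTruth,
    molecules_per_cell: int,
    error_rate: float,
    truncation_prob: float,
    seed: int,
    *,
    trunc_max_frac: float = 0.65,
) -> list[SimRead]:
    """Emit one read per cDNA molecule, with 5'-only truncation.

    Truncation (probability ``truncation_prob`` per molecule) removes a
    uniform-length prefix of the cDNA 5' end, up to ``trunc_max_frac`` of
    the transcript; the polyT-anchored 3' end is always retained.
    """
    if len(truth.annotation) == 0:
        raise InputError("empty annotation")
    if not truth.cells:
        raise InputError("generate_cells must run before simulate_long_reads")
    if not (0.0 <= error_rate <= 0.1):
        raise InputError("error_rate must be in [0, 0.1]")
    rng = np.random.default_rng(seed)
    cfg = truth.config

    genes = sorted(truth.annotation.genes)
    noncoding = [g for g in genes if truth.gene_is_noncoding(g)]
    coding = [g for g in genes if not truth.gene_is_noncoding(g)]

    reads: list[SimRead] = []
    counter = len(truth.molecule_log)
    for bc, cell in truth.cells.items():
        mixtures = truth.cluster_mixtures[cell.cluster]
        nc_frac = truth.noncoding_expression.get(cell.condition, 0.0)
        for _ in range(molecules_per_cell):
            if noncoding and coding:
                pool = noncoding if rng.random() < nc_frac else coding
            else:
                pool = genes
            gene = pool[int(rng.integers(0, len(pool)))]
            mix = mixtures[gene]
            txs = list(mix)
            tx = txs[int(rng.choice(len(txs), p=np.array(list(mix.values()))))]
            seq = truth.transcript_seq(tx)
            t0 = 0
            if truncation_prob > 0 and rng.random() < truncation_prob:
                t0 = int(rng.uniform(0, trunc_max_frac) * len(seq))
            umi = random_dna(rng, cfg.umi_length)
            mol = MoleculeRecord(
                mol_id=f"m{counter:07d}",
                barcode=bc,
                umi=umi,
                kind="normal",
                transcript_id=tx,
                trunc_offset=t0,
            )
            counter += 1
            reads.append(_emit_read(truth, mol, seq[t0:], rng, error_rate))
    return reads


# --------------------------------------------------------------------------
# planted novel exons


def _free_intervals(intron: Interval, blocked: Sequence[Interval]) -> list[Interval]:
    s, e = intron
    cuts = sorted((max(s, a), min(e, b)) for a, b in blocked if a < e and s < b)
    free, pos = [], s
    for a, b in cuts:
        if a > pos:
            free.append((pos, a))
        pos = max(pos, b)
    if pos < e:
        free.append((pos, e))
    return free


def plant_novel_exons(
    truth: SyntheticTruth,
    n_exons: int,
    exon_len: Union[int, tuple[int, int]],
    support: Union[int, tuple[int, int]],
    seed: int,
    *,
    error_rate: float = 0.0,
) -> list[SimRead]:
    """Plant unannotated intron-internal exons and emit their support reads.

    ``exon_len`` and ``support`` may be scalars or inclusive ``(lo, hi)``
    ranges sampled per exon. Each support read follows the host gene's
    primary isoform with the planted exon spliced in at full length.
    """
    if not truth.cells:
        raise InputError("generate_cells must run before plant_novel_exons")
    rng = np.random.default_rng(seed)
    len_lo, len_hi = (exon_len, exon_len) if isinstance(exon_len, int) else exon_len
    sup_lo, sup_hi = (support, support) if isinstance(support, int) else support

    barcodes = sorted(truth.cells)
    planted_blocks: dict[str, list[Interval]] = {}
    reads: list[SimRead] = []
    counter = len(truth.molecule_log)

    genes = sorted(truth.annotation.genes)
    rng.shuffle(genes)
    placed = 0
    for gene_id in genes + genes:  # allow a second pass with different draws
        if placed >= n_exons:
            break
        elen = int(rng.integers(len_lo, len_hi + 1))
        nsup = int(rng.integers(sup_lo, sup_hi + 1))
        host = truth.annotation[f"{gene_id}.t1"]
        gene_exons = sorted(truth.annotation.exons_of_gene(gene_id))
        blocked = gene_exons + planted_blocks.get(gene_id, [])
        choices = []
        for jx_genomic, intron in enumerate(host.junctions):
            for fs, fe in _free_intervals(intron, blocked):
                # strictly inside both the free window and the intron
                lo = max(fs, intron[0] + 1)
                hi = min(fe, intron[1] - 1)
                if hi - lo >= elen:
                    choices.append((jx_genomic, intron, lo, hi))
        if not choices:
            continue
        jx_genomic, intron, lo, hi = choices[int(rng.integers(0, len(choices)))]
        start = int(rng.integers(lo, hi - elen + 1))
        interval = (start, start + elen)
        planted_blocks.setdefault(gene_id, []).append(interval)

        n_junc = len(host.junctions)
        jx_tx = jx_genomic if host.strand == "+" else n_junc - 1 - jx_genomic
        p = host.junction_tx_positions()[jx_tx]
        exon = PlantedExon(
            chrom=host.chrom,
            start=start,
            end=start + elen,
            gene_id=gene_id,
            transcript_id=host.transcript_id,
            intron=intron,
            tx_junction_pos=p,
        )
        truth.planted_novel_exons.append(exon)
        placed += 1

        gseq = truth.genome[host.chrom][start : start + elen]
        eseq = gseq if host.strand == "+" else revcomp(gseq)
        tseq = truth.transcript_seq(host.transcript_id)
        cdna = tseq[:p] + eseq + tseq[p:]
        for _ in range(nsup):
            bc = barcodes[int(rng.integers(0, len(barcodes)))]
            mol = MoleculeRecord(
                mol_id=f"m{counter:07d}",
                barcode=bc,
                umi=random_dna(rng, truth.config.umi_length),
                kind="novel_exon",
                transcript_id=host.transcript_id,
                novel_exon=exon,
            )
            counter += 1
            reads.append(_emit_read(truth, mol, cdna, rng, error_rate))

    if placed < n_exons:
        raise CapacityError(f"only {placed}/{n_exons} novel exons could be placed")
    return reads


# --------------------------------------------------------------------------
# immunoglobulin molecules


def make_ig_segments(
    n_v: int, n_j: int, seed: int, *, v_len: int = 290, j_len: int = 38, c_len: int = 320
) -> tuple[dict[str, str], dict[str, str], str]:
    """Synthetic V/J/constant kappa-like segment sequences."""
    rng = np.random.default_rng(seed)
    vs = {f"IGKV{i + 1}": random_dna(rng, v_len) for i in range(n_v)}
    js = {f"IGKJ{i + 1}": random_dna(rng, j_len) for i in range(n_j)}
    return vs, js, random_dna(rng, c_len)


def _load_segments(src: Union[str, Path, Mapping[str, str]]) -> dict[str, str]:
    if isinstance(src, Mapping):
        return dict(src)
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(src), "fasta"):
        if rec.id in out:
            raise InputError(f"duplicate segment id {rec.id}")
        out[rec.id] = str(rec.seq).upper()
    return out


def simulate_ig_molecules(
    truth: SyntheticTruth,
    v_segments: Union[str, Path, Mapping[str, str]],
    j_segments: Union[str, Path, Mapping[str, str]],
    c_segment: str,
    n_molecules: int,
    seed: int,
    *,
    cells: Optional[Sequence[str]] = None,
    error_rate: float = 0.0,
) -> list[SimRead]:
    """Emit VJ-recombined molecules ([V][J][C] cDNA) in the standard layout."""
    vs, js = _load_segments(v_segments), _load_segments(j_segments)
    if not vs or not js or not c_segment:
        raise InputError("need at least one V segment, one J segment and a constant segment")
    if not truth.cells:
        raise InputError("generate_cells must run before simulate_ig_molecules")
    rng = np.random.default_rng(seed)
    pool = sorted(cells) if cells is not None else sorted(truth.cells)
    v_ids, j_ids = sorted(vs), sorted(js)

    reads: list[SimRead] = []
    counter = len(truth.molecule_log)
    for _ in range(n_molecules):
        v = v_ids[int(rng.integers(0, len(v_ids)))]
        j = j_ids[int(rng.integers(0, len(j_ids)))]
        bc = pool[int(rng.integers(0, len(pool)))]
        mol = MoleculeRecord(
            mol_id=f"m{counter:07d}",
            barcode=bc,
            umi=random_dna(rng, truth.config.umi_length),
            kind="ig",
            vj=(v, j),
        )
        counter += 1
        truth.planted_vj[mol.mol_id] = (v, j)
        reads.append(_emit_read(truth, mol, vs[v] + js[j] + c_segment, rng, error_rate))
    return reads


# --------------------------------------------------------------------------
# truth alignments + file writers


def _remaining_blocks(t: TranscriptModel, trunc_offset: int) -> list[Interval]:
    """Genomic exon blocks covered by the cDNA after 5' truncation."""
    out: list[Interval] = []
    skip = trunc_offset
    for s, e in t.exons_in_tx_order():
        L = e - s
        if skip >= L:
            skip -= L
            continue
        out.append((s + skip, e) if t.strand == "+" else (s, e - skip))
        skip = 0
    return sorted(out)


def write_fastq(reads: Iterable[SimRead], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.seq}\n+\n{QUAL_CHAR * len(r.seq)}\n")


def write_fasta(seqs: Mapping[str, str], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n{seqs[name]}\n")


def write_whitelist(truth: SyntheticTruth, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for bc, cell in truth.cells.items():
            fh.write(f"{bc}\t{cell.cluster}\t{cell.sample}\t{cell.condition}\n")


def _clip_len(truth: SyntheticTruth) -> int:
    return truth.config.prefix_length + TAIL_LEN


def write_truth_sam(
    reads: Sequence[SimRead],
    truth: SyntheticTruth,
    path: Union[str, Path],
    space: str,
) -> int:
    """Write error-free truth alignments; returns the number of records.

    ``space`` is ``'genome'`` or ``'transcriptome'``. Immunoglobulin
    molecules have no reference in either space and are skipped.
    """
    if space not in ("genome", "transcriptome"):
        raise ValueError(f"bad alignment space {space!r}")
    clip = _clip_len(truth)
    if space == "genome":
        refs = sorted(truth.genome)
        lengths = [len(truth.genome[c]) for c in refs]
    else:
        refs = sorted(truth.annotation.transcripts)
        lengths = [truth.annotation[t].length for t in refs]
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": r, "LN": ln} for r, ln in zip(refs, lengths)],
    }
    ref_index = {r: i for i, r in enumerate(refs)}

    n = 0
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for r in reads:
            mol = r.molecule
            if mol.kind == "ig":
                continue
            t = truth.annotation[mol.transcript_id]
            sense = r.sense_seq
            errors_in_cdna = sum(1 for p in r.error_positions if p >= clip)
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.read_id
            a.mapping_quality = 60

            if space == "genome":
                blocks = _remaining_blocks(t, mol.trunc_offset)
                if mol.novel_exon is not None:
                    blocks = sorted(blocks + [(mol.novel_exon.start, mol.novel_exon.end)])
                ref_forward_is_sense = t.strand == "-"
                seq_rf = sense if ref_forward_is_sense else revcomp(sense)
                cigar: list[tuple[int, int]] = []
                if ref_forward_is_sense:
                    cigar.append((4, clip))
                for i, (s, e) in enumerate(blocks):
                    if i:
                        cigar.append((3, s - blocks[i - 1][1]))
                    cigar.append((0, e - s))
                if not ref_forward_is_sense:
                    cigar.append((4, clip))
                a.reference_id = ref_index[t.chrom]
                a.reference_start = blocks[0][0]
                a.is_reverse = r.flipped if ref_forward_is_sense else not r.flipped
                a.cigar = cigar
                a.set_tag("NM", errors_in_cdna)
            else:
                L = t.length
                seq_rf = revcomp(sense)
                if mol.novel_exon is not None:
                    p = mol.novel_exon.tx_junction_pos
                    elen = mol.novel_exon.length
                    cigar = [(0, p), (1, elen), (0, L - p), (4, clip)]
                    nm = errors_in_cdna + elen
                    start = 0
                else:
                    cigar = [(0, L - mol.trunc_offset), (4, clip)]
                    nm = errors_in_cdna
                    start = mol.trunc_offset
                a.reference_id = ref_index[t.transcript_id]
                a.reference_start = start
                a.is_reverse = not r.flipped
                a.cigar = cigar
                a.set_tag("NM", nm)

            a.query_sequence = seq_rf
            a.query_qualities = pysam.qualitystring_to_array(QUAL_CHAR * len(seq_rf))
            out.write(a)
            n += 1
    return n
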