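"""Shared fixtures: one seeded synthetic dataset, processed once."""

from types import SimpleNamespace

import pytest

from sciso import synth
from sciso.demux import demultiplex
from sciso.isoquant import JunctionIndex, assign_read, parse_alignments, snap_junctions
from sciso.models import TranscriptModel, Annotation


@pytest.fixture(scope="session")
def dataset(tmp_path_factory):
    """A small end-to-end dataset: 5 genes / up to 3 isoforms, 10 cells in
    2 clusters, 20 molecules per cell at 1% error, no truncation, plus two
    planted 120-nt novel exons with 3 support reads each."""
    truth = synth.generate_annotation(5, 3, seed=1)
    synth.generate_cells(truth, 10, 2, 1.0, seed=3)
    reads = synth.simulate_long_reads(truth, 20, 0.01, 0.0, seed=5)
    reads = reads + synth.plant_novel_exons(truth, 2, 120, 3, seed=7, error_rate=0.01)
    d = tmp_path_factory.mktemp("dataset")
    genome_sam, tx_sam = d / "genome.sam", d / "tx.sam"
    synth.write_truth_sam(reads, truth, genome_sam, "genome")
    synth.write_truth_sam(reads, truth, tx_sam, "transcriptome")
    raw_genome_alns, _ = parse_alignments(genome_sam, "genome")
    tx_alns, _ = parse_alignments(tx_sam, "transcriptome")
    jindex = JunctionIndex(truth.annotation)
    genome_alns = [snap_junctions(a, jindex) for a in raw_genome_alns]
    demux_result = demultiplex([(r.read_id, r.seq) for r in reads], sorted(truth.cells))

    records = demux_result.records_by_id()
    by_read = {}
    for a in genome_alns:
        by_read.setdefault(a.read_id, []).append(a)
    assignments, pairs = [], []
    for rid in sorted(by_read):
        rec = records.get(rid)
        if rec is None or rec.barcode is None:
            continue
        a = assign_read(by_read[rid], truth.annotation, demux=rec)
        assignments.append(a)
        pairs.append((a, by_read[rid][0]))

    return SimpleNamespace(
        truth=truth,
        reads=reads,
        dir=d,
        genome_sam=genome_sam,
        tx_sam=tx_sam,
        raw_genome_alns=raw_genome_alns,
        genome_alns=genome_alns,
        tx_alns=tx_alns,
        demux=demux_result,
        assignments=assignments,
        assignment_pairs=pairs,
    )


def make_coding_case():
    """Plus-strand gene; exon1 (100,400), exon2 (900,1200), UTR-only exon3
    (1500,1800); CDS from 130 to 1100 written as a stop-free ORF ending in
    TAA. Intronic sequence is all-C so that planted exon bodies cannot
    introduce stop codons in any frame. Returns (genome, annotation,
    novel-model factory)."""
    import numpy as np

    from sciso.models import NovelTranscript
    from sciso.models import CASSETTE_EXON
    from sciso.synth import _random_codon, random_dna

    rng = np.random.default_rng(99)
    genome = list(random_dna(rng, 2500))
    prov = TranscriptModel(
        "gC.t1", "gC", "chr1", "+",
        ((100, 400), (900, 1200), (1500, 1800)),
        biotype="protein_coding", cds=(130, 1100),
    )
    positions = [p for s, e in prov.exons for p in range(s, e) if 130 <= p < 1100]
    n_codons = len(positions) // 3
    orf = "".join(_random_codon(rng) for _ in range(n_codons - 1)) + "TAA"
    for pos, base in zip(positions, orf):
        genome[pos] = base
    for p in range(400, 900):
        genome[p] = "C"
    for p in range(1200, 1500):
        genome[p] = "C"

    def novel_with_exon(exon):
        exons = tuple(sorted([(100, 400), (900, 1200), (1500, 1800), exon]))
        t = TranscriptModel("gC.n1", "gC", "chr1", "+", exons, biotype="novel")
        return NovelTranscript(
            model=t, event=CASSETTE_EXON, support={"s1": 5}, provenance="gC.t1"
        )

    return {"chr1": "".join(genome)}, Annotation([prov]), novel_with_exon


@pytest.fixture()
def coding_case():
    return make_coding_case()


@pytest.fixture()
def toy_gene():
    """A hand-built plus-strand four-exon gene with a CDS, for event
    classification and coding tests. Junctions: (100,200) (300,400) (500,600)."""
    t = TranscriptModel(
        "toyG.t1",
        "toyG",
        "chrT",
        "+",
        ((0, 100), (200, 300), (400, 500), (600, 700)),
        biotype="protein_coding",
        cds=(30, 670),
    )
    return Annotation([t])
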