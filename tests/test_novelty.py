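"""Novel-exon discovery, event classification, filtering, coding calls."""

import numpy as np
import pytest

from sciso.config import DEFAULT_CONFIG
from sciso.isoquant import JunctionIndex, snap_junctions
from sciso.models import (
    ALT_3SS,
    ALT_5SS,
    CASSETTE_EXON,
    EVENT_LABELS,
    INTRON_RETENTION,
    Annotation,
    Insertion,
    IsoformAssignment,
    NOVEL_COMBINATION,
    NOVEL_JUNCTION,
    NOVEL_JUNCTION_COMBINATION,
    NovelTranscript,
    SplicedAlignment,
    TranscriptModel,
)
from sciso.novelty import (
    InsertCandidate,
    assess_coding,
    classify_novel_transcripts,
    confirm_novel_exons,
    detect_insert_candidates,
    filter_novel_transcripts,
    flag_internal_priming,
    remove_matched_antisense,
)
from sciso import synth


def tx_aln(read_id, tx, tx_len, insertions):
    return SplicedAlignment(
        read_id=read_id,
        target_kind="transcriptome",
        target_id=tx,
        is_reverse=False,
        blocks=[(0, tx_len)],
        gap_is_splice=[],
        insertions=list(insertions),
        nm=sum(i.length for i in insertions),
        query_length=tx_len + sum(i.length for i in insertions),
        aligned_query_bases=tx_len + sum(i.length for i in insertions),
    )


def g_aln(read_id, blocks, chrom="chr1"):
    return SplicedAlignment(
        read_id=read_id,
        target_kind="genome",
        target_id=chrom,
        is_reverse=False,
        blocks=list(blocks),
        gap_is_splice=[True] * (len(blocks) - 1),
        insertions=[],
        nm=0,
        query_length=sum(e - s for s, e in blocks),
        aligned_query_bases=sum(e - s for s, e in blocks),
    )


class TestInsertCandidates:
    def _annotation(self):
        # two exons of 300 nt each; junction at transcript position 300
        t = TranscriptModel("gX.t1", "gX", "chr1", "+", ((1000, 1300), (2000, 2300)))
        return Annotation([t])

    def test_insertion_at_junction_is_candidate(self):
        ann = self._annotation()
        aln = tx_aln("r1", "gX.t1", 600, [Insertion(query_pos=300, length=25, target_pos=300)])
        cands = detect_insert_candidates([aln], ann)
        assert len(cands) == 1 and cands[0].junction_index == 0

    def test_mid_exon_insertion_excluded(self):
        ann = self._annotation()
        aln = tx_aln("r1", "gX.t1", 600, [Insertion(query_pos=150, length=25, target_pos=150)])
        assert detect_insert_candidates([aln], ann) == []

    def test_twenty_nt_insert_below_threshold(self):
        ann = self._annotation()
        aln = tx_aln("r1", "gX.t1", 600, [Insertion(query_pos=300, length=20, target_pos=300)])
        assert detect_insert_candidates([aln], ann) == []

    def test_placement_tolerance(self):
        ann = self._annotation()
        near = tx_aln("r1", "gX.t1", 600, [Insertion(query_pos=296, length=30, target_pos=296)])
        far = tx_aln("r2", "gX.t1", 600, [Insertion(query_pos=290, length=30, target_pos=290)])
        assert len(detect_insert_candidates([near], ann)) == 1  # 4 nt off, within 5
        assert detect_insert_candidates([far], ann) == []  # 10 nt off


class TestConfirmNovelExons:
    def test_planted_exons_recovered_exactly(self, dataset):
        truth = dataset.truth
        cands = detect_insert_candidates(dataset.tx_alns, truth.annotation)
        calls = confirm_novel_exons(cands, dataset.genome_alns, truth.annotation)
        planted = {(e.chrom, e.start, e.end) for e in truth.planted_novel_exons}
        called = {(c.chrom, c.start, c.end) for c in calls}
        assert called == planted
        assert all(c.n_support == 3 for c in calls)

    def test_single_read_support_rejected(self):
        truth = synth.generate_annotation(4, 1, seed=21)
        synth.generate_cells(truth, 4, 1, 1.0, seed=21)
        reads = synth.plant_novel_exons(truth, 2, 60, 1, seed=22)
        import tempfile, os

        with tempfile.TemporaryDirectory() as d:
            from sciso.isoquant import parse_alignments

            synth.write_truth_sam(reads, truth, os.path.join(d, "t.sam"), "transcriptome")
            synth.write_truth_sam(reads, truth, os.path.join(d, "g.sam"), "genome")
            tx_alns, _ = parse_alignments(os.path.join(d, "t.sam"), "transcriptome")
            g_alns, _ = parse_alignments(os.path.join(d, "g.sam"), "genome")
        cands = detect_insert_candidates(tx_alns, truth.annotation)
        assert len(cands) == 2  # candidates exist ...
        calls = confirm_novel_exons(cands, g_alns, truth.annotation)
        assert calls == []  # ... but support of 1 read is below the floor

    def test_short_plant_rejected_at_candidate_stage(self):
        truth = synth.generate_annotation(4, 1, seed=23)
        synth.generate_cells(truth, 4, 1, 1.0, seed=23)
        reads = synth.plant_novel_exons(truth, 2, 20, 3, seed=24)
        import tempfile, os

        with tempfile.TemporaryDirectory() as d:
            from sciso.isoquant import parse_alignments

            synth.write_truth_sam(reads, truth, os.path.join(d, "t.sam"), "transcriptome")
            tx_alns, _ = parse_alignments(os.path.join(d, "t.sam"), "transcriptome")
        assert detect_insert_candidates(tx_alns, truth.annotation) == []

    def test_blocks_differing_within_tolerance_merge(self):
        t = TranscriptModel("gY.t1", "gY", "chr1", "+", ((0, 300), (1000, 1300)))
        ann = Annotation([t])
        cands = [
            InsertCandidate("r1", "gY.t1", 300, 60, 0, 300),
            InsertCandidate("r2", "gY.t1", 300, 60, 0, 300),
        ]
        alns = [
            g_aln("r1", [(0, 300), (500, 560), (1000, 1300)]),
            g_aln("r2", [(0, 300), (502, 562), (1000, 1300)]),  # 2 nt shifted
        ]
        calls = confirm_novel_exons(cands, alns, ann, min_exon_support=2)
        assert len(calls) == 1 and calls[0].n_support == 2

    def test_block_overlapping_known_exon_discarded(self):
        t1 = TranscriptModel("gZ.t1", "gZ", "chr1", "+", ((0, 300), (1000, 1300)))
        # sibling isoform contributes an exon inside gZ.t1's intron
        t2 = TranscriptModel("gZ.t2", "gZ", "chr1", "+", ((0, 300), (600, 700), (1000, 1300)))
        ann = Annotation([t1, t2])
        cands = [
            InsertCandidate(f"r{i}", "gZ.t1", 300, 100, 0, 300) for i in range(2)
        ]
        alns = [g_aln(f"r{i}", [(0, 300), (620, 720), (1000, 1300)]) for i in range(2)]
        assert confirm_novel_exons(cands, alns, ann, min_exon_support=2) == []

    def test_candidate_without_genome_alignment_dropped(self):
        t = TranscriptModel("gY.t1", "gY", "chr1", "+", ((0, 300), (1000, 1300)))
        ann = Annotation([t])
        cands = [InsertCandidate("ghost", "gY.t1", 300, 60, 0, 300)]
        assert confirm_novel_exons(cands, [], ann, min_exon_support=1) == []


def novel_item(gene, chain, blocks, read_id="r1", bc=None, category=NOVEL_COMBINATION):
    a = IsoformAssignment(read_id, bc, "U1", category, gene_id=gene)
    return a, g_aln(read_id, blocks, chrom="chrT")


class TestClassifyEvents:
    def test_skipped_exon_is_cassette(self, toy_gene):
        # toy gene junctions: (100,200) (300,400) (500,600); skip exon 2
        items = [novel_item("toyG", None, [(0, 100), (200, 300), (600, 700)])]
        items[0][1].gap_is_splice[:] = [True, True]
        # chain (100,200),(300,600): exon 3 skipped
        models = classify_novel_transcripts(items, toy_gene)
        assert len(models) == 1 and models[0].event == CASSETTE_EXON

    def test_moved_donor_is_alt5ss(self, toy_gene):
        # plus strand: donor of junction 1 moved +12 (212 unannotated)
        items = [novel_item("toyG", None, [(0, 100), (200, 312), (400, 500), (600, 700)], category=NOVEL_JUNCTION)]
        models = classify_novel_transcripts(items, toy_gene)
        assert models[0].event == ALT_5SS

    def test_moved_acceptor_is_alt3ss(self, toy_gene):
        items = [novel_item("toyG", None, [(0, 100), (212, 300), (400, 500), (600, 700)], category=NOVEL_JUNCTION)]
        models = classify_novel_transcripts(items, toy_gene)
        assert models[0].event == ALT_3SS

    def test_known_sites_new_pairing_is_combination(self, toy_gene):
        # donor of intron 1 (100) joined to acceptor of intron 3 (600)
        items = [novel_item("toyG", None, [(0, 100), (600, 700)])]
        models = classify_novel_transcripts(items, toy_gene)
        assert models[0].event == NOVEL_JUNCTION_COMBINATION

    def test_retained_intron(self, toy_gene):
        # junction (300,400) missing, covered by one exon block
        items = [novel_item("toyG", None, [(0, 100), (200, 500), (600, 700)])]
        models = classify_novel_transcripts(items, toy_gene)
        assert models[0].event == INTRON_RETENTION

    def test_included_novel_exon_is_cassette(self, toy_gene):
        # new exon (330, 370) inside intron (300, 400)
        items = [novel_item("toyG", None, [(0, 100), (200, 300), (330, 370), (400, 500), (600, 700)], category=NOVEL_JUNCTION)]
        models = classify_novel_transcripts(items, toy_gene)
        assert models[0].event == CASSETTE_EXON

    def test_reads_with_identical_chains_collapse(self, toy_gene):
        items = [
            novel_item("toyG", None, [(0, 100), (200, 300), (600, 700)], read_id="r1", bc="B1"),
            novel_item("toyG", None, [(10, 100), (200, 300), (600, 690)], read_id="r2", bc="B2"),
        ]
        models = classify_novel_transcripts(items, toy_gene, {"B1": "s1", "B2": "s2"})
        assert len(models) == 1
        assert models[0].support == {"s1": 1, "s2": 1}

    def test_every_novel_read_gets_exactly_one_label(self, dataset):
        models = classify_novel_transcripts(
            dataset.assignment_pairs, dataset.truth.annotation
        )
        assert models, "expected planted novel-exon reads to form models"
        for m in models:
            assert m.event in EVENT_LABELS


class TestFilter:
    def _model(self, support):
        t = TranscriptModel("n1", "g1", "chr1", "+", ((0, 100), (200, 300)))
        return NovelTranscript(model=t, event=CASSETTE_EXON, support=support, provenance="g1.t1")

    def test_reads_in_single_sample_rejected(self):
        kept = filter_novel_transcripts([self._model({"s1": 5, "s2": 0, "s3": 0})], 5, 3)
        assert kept == []

    def test_spread_support_retained_under_default_semantics(self):
        m = self._model({"s1": 2, "s2": 2, "s3": 1})
        assert filter_novel_transcripts([m], 5, 3) == [m]

    def test_per_sample_semantics_stricter(self):
        m = self._model({"s1": 2, "s2": 2, "s3": 1})
        assert filter_novel_transcripts([m], 5, 3, mode="per_sample") == []
        m2 = self._model({"s1": 5, "s2": 6, "s3": 5})
        assert filter_novel_transcripts([m2], 5, 3, mode="per_sample") == [m2]

    def test_monotone_in_n_and_k_over_random_tables(self):
        rng = np.random.default_rng(11)
        models = [
            self._model({f"s{j}": int(rng.integers(0, 6)) for j in range(4)})
            for _ in range(100)
        ]
        def names(kept):
            return {id(m) for m in kept}

        strict = names(filter_novel_transcripts(models, 5, 3))
        loose = names(filter_novel_transcripts(models, 2, 2))
        assert strict <= loose
        for mode in ("total", "per_sample"):
            for n1, k1, n2, k2 in [(5, 3, 4, 3), (5, 3, 5, 2), (4, 2, 2, 2), (3, 3, 2, 1)]:
                assert names(filter_novel_transcripts(models, n1, k1, mode)) <= names(
                    filter_novel_transcripts(models, n2, k2, mode)
                )


class TestAntisenseRemoval:
    def _annotation(self):
        return Annotation(
            [TranscriptModel("g1.t1", "g1", "chr1", "+", ((0, 100), (200, 300)))]
        )

    def _novel(self, strand, exons):
        t = TranscriptModel("n1", "gN", "chr1", strand, exons)
        return NovelTranscript(model=t, event=CASSETTE_EXON, support={"s1": 5}, provenance="g1.t1")

    def test_perfect_antisense_mirror_removed(self):
        ann = self._annotation()
        m = self._novel("-", ((0, 100), (200, 300)))
        assert remove_matched_antisense([m], ann) == []

    def test_antisense_with_different_junction_kept(self):
        ann = self._annotation()
        m = self._novel("-", ((0, 100), (210, 300)))
        assert remove_matched_antisense([m], ann) == [m]

    def test_sense_model_never_removed(self):
        ann = self._annotation()
        m = self._novel("+", ((0, 100), (200, 300)))
        assert remove_matched_antisense([m], ann) == [m]


class TestAssessCoding:
    def test_in_frame_297nt_cassette_is_coding(self, coding_case):
        genome, ann, novel = coding_case
        m = novel((450, 747))  # 297 nt inside the CDS
        assert assess_coding(m, ann, genome) is True
        assert m.coding is True

    def test_22nt_insertion_is_frameshift(self, coding_case):
        genome, ann, novel = coding_case
        m = novel((450, 472))
        assert assess_coding(m, ann, genome) is False

    def test_utr_event_inherits_provenance_status(self, coding_case):
        genome, ann, novel = coding_case
        m = novel((1250, 1294))  # 44 nt in the 3' UTR intron
        assert assess_coding(m, ann, genome) is True

    def test_no_cds_gives_unknown(self, coding_case):
        genome, _, novel = coding_case
        prov = TranscriptModel("gC.t1", "gC", "chr1", "+", ((100, 400), (900, 1200)), biotype="lncRNA")
        ann = Annotation([prov])
        m = novel((450, 747))
        assert assess_coding(m, ann, genome) is None

    def test_in_frame_with_stop_codon_is_noncoding(self, coding_case):
        genome, ann, novel = coding_case
        g = list(genome["chr1"])
        # poison the planted exon with stops in every frame
        g[450 : 450 + 297] = list("TAA" * 99)
        m = novel((450, 747))
        assert assess_coding(m, ann, {"chr1": "".join(g)}) is False


class TestInternalPriming:
    def test_a_rich_downstream_flags_plus_strand(self):
        genome = {"chr1": "C" * 100 + "A" * 20 + "C" * 50}
        aln = g_aln("r1", [(50, 100)])
        assert flag_internal_priming(aln, genome, "+") is True
        genome2 = {"chr1": "C" * 100 + "A" * 10 + "G" + "A" * 9 + "C" * 50}
        assert flag_internal_priming(aln, genome2, "+") is False

    def test_t_rich_upstream_flags_minus_strand(self):
        genome = {"chr1": "C" * 80 + "T" * 20 + "G" * 100}
        aln = g_aln("r1", [(100, 150)])
        assert flag_internal_priming(aln, genome, "-") is True
        assert flag_internal_priming(aln, genome, "+") is False
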