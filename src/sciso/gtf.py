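"""GTF reading and writing for transcript models.

Reading goes through :mod:`gffutils` (in-memory sqlite database); writing
emits standard 1-based inclusive GTF with ``gene_id``/``transcript_id``
attributes plus ``transcript_biotype``. A written annotation round-trips
losslessly through :func:`read_gtf`.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Union

import gffutils

from .models import Annotation, TranscriptModel

PathLike = Union[str, Path]


def write_gtf(annotation: Iterable[TranscriptModel], path: PathLike, source: str = "sciso") -> None:
    txs = sorted(annotation, key=lambda t: (t.chrom, t.start, t.gene_id, t.transcript_id))
    by_gene: dict[str, list[TranscriptModel]] = {}
    for t in txs:
        by_gene.setdefault(t.gene_id, []).append(t)

    def line(chrom, feat, start, end, strand, attrs):
        a = " ".join(f'{k} "{v}";' for k, v in attrs)
        return f"{chrom}\t{source}\t{feat}\t{start + 1}\t{end}\t.\t{strand}\t.\t{a}\n"

    with open(path, "w") as fh:
        seen_gene = set()
        for t in txs:
            if t.gene_id not in seen_gene:
                seen_gene.add(t.gene_id)
                sibs = by_gene[t.gene_id]
                gs, ge = min(x.start for x in sibs), max(x.end for x in sibs)
                fh.write(line(t.chrom, "gene", gs, ge, t.strand, [("gene_id", t.gene_id)]))
            attrs = [
                ("gene_id", t.gene_id),
                ("transcript_id", t.transcript_id),
                ("transcript_biotype", t.biotype),
            ]
            fh.write(line(t.chrom, "transcript", t.start, t.end, t.strand, attrs))
            for s, e in t.exons:
                fh.write(line(t.chrom, "exon", s, e, t.strand, attrs))
            if t.cds is not None:
                cs, ce = t.cds
                for s, e in t.exons:
                    os_, oe = max(s, cs), min(e, ce)
                    if os_ < oe:
                        fh.write(line(t.chrom, "CDS", os_, oe, t.strand, attrs))


def read_gtf(path: PathLike) -> Annotation:
    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        merge_strategy="create_unique",
    )
    models: list[TranscriptModel] = []
    for tf in db.features_of_type("transcript"):
        tid = tf.attributes["transcript_id"][0]
        gid = tf.attributes["gene_id"][0]
        biotype = tf.attributes.get("transcript_biotype", ["protein_coding"])[0]
        exons = []
        cds_lo, cds_hi = None, None
        for child in db.children(tf, featuretype=("exon", "CDS")):
            iv = (child.start - 1, child.end)
            if child.featuretype == "exon":
                exons.append(iv)
            else:
                cds_lo = iv[0] if cds_lo is None else min(cds_lo, iv[0])
                cds_hi = iv[1] if cds_hi is None else max(cds_hi, iv[1])
        cds = (cds_lo, cds_hi) if cds_lo is not None else None
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gid,
                chrom=tf.seqid,
                strand=tf.strand,
                exons=tuple(sorted(exons)),
                biotype=biotype,
                cds=cds,
            )
        )
    return Annotation(models)
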