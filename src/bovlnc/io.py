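"""GTF / FASTA / TSV input and output.

GTF is read with gffutils and written as plain exon feature lines carrying
``gene_id``, ``transcript_id`` and ``gene_biotype`` attributes.  Internal
coordinates are 0-based half-open; GTF is 1-based inclusive.
"""

from __future__ import annotations

import os
from typing import Mapping

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import AnnotationSet, TranscriptModel


def read_gtf(path: str | os.PathLike) -> AnnotationSet:
    """Load an annotation from a GTF file (exon features only)."""
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    by_tx: dict[str, dict] = {}
    for feat in db.features_of_type("exon", order_by=("seqid", "start")):
        tid = feat.attributes["transcript_id"][0]
        rec = by_tx.setdefault(
            tid,
            {
                "chrom": feat.seqid,
                "strand": feat.strand,
                "gene_id": feat.attributes["gene_id"][0],
                "biotype": feat.attributes.get("gene_biotype", ["protein_coding"])[0],
                "exons": [],
            },
        )
        # GTF 1-based inclusive -> 0-based half-open
        rec["exons"].append((feat.start - 1, feat.end))
    ann = AnnotationSet()
    for tid in sorted(by_tx):
        rec = by_tx[tid]
        tx = TranscriptModel(
            id=tid,
            chrom=rec["chrom"],
            strand=rec["strand"],
            exons=tuple(sorted(rec["exons"])),
        )
        ann.add(tx, rec["gene_id"], rec["biotype"])
    return ann


def write_gtf(ann: AnnotationSet, path: str | os.PathLike, source: str = "bovlnc") -> None:
    """Write an annotation as GTF exon lines, deterministically ordered."""
    with open(path, "w") as fh:
        for tid in sorted(ann.transcripts):
            tx = ann.transcripts[tid]
            gid = ann.gene_of[tid]
            biotype = ann.biotype[gid]
            for s, e in tx.exons:
                attrs = (
                    f'gene_id "{gid}"; transcript_id "{tid}"; '
                    f'gene_biotype "{biotype}";'
                )
                fh.write(
                    f"{tx.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{tx.strand}\t.\t{attrs}\n"
                )


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read sequences into an id -> uppercase string mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | os.PathLike, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seqs[sid]), id=sid, description="") for sid in sorted(seqs)
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
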