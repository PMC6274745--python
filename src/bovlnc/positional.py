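"""Genomic-location/orientation classification of lncRNAs.

Each lncRNA is assigned to one of 11 classes relative to the protein-coding
annotation.  The taxonomy is a reconstruction built from the standard
location/orientation vocabulary of lncRNA catalogs: intergenic (>1 kb from
any gene), exonic overlap (sense/antisense), intronic (sense/antisense), a
coding gene contained in a lncRNA intron, within 1 kb upstream or
downstream of a gene (sense/antisense), and a divergent pair sharing a
bidirectional promoter (opposite strands, transcription start sites within
500 bp).

Precedence when several classes are geometrically eligible:
exonic overlap > intronic > gene-in-lncRNA-intron > upstream/downstream
within 1 kb > bidirectional promoter > intergenic.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass

from .models import AnnotationSet, TranscriptModel

logger = logging.getLogger(__name__)


class PositionalClass(enum.Enum):
    INTERGENIC_GT1KB = "intergenic_gt1kb"
    EXONIC_OVERLAP_SENSE = "exonic_overlap_sense"
    EXONIC_OVERLAP_ANTISENSE = "exonic_overlap_antisense"
    UPSTREAM_1KB_SENSE = "upstream_1kb_sense"
    UPSTREAM_1KB_ANTISENSE = "upstream_1kb_antisense"
    DOWNSTREAM_1KB_SENSE = "downstream_1kb_sense"
    DOWNSTREAM_1KB_ANTISENSE = "downstream_1kb_antisense"
    INTRONIC_SENSE = "intronic_sense"
    INTRONIC_ANTISENSE = "intronic_antisense"
    GENE_IN_LNCRNA_INTRON = "gene_in_lncrna_intron"
    BIDIRECTIONAL_PROMOTER_SHARED = "bidirectional_promoter_shared"


# most specific first; used to resolve multi-gene eligibility
_PRECEDENCE = (
    PositionalClass.EXONIC_OVERLAP_SENSE,
    PositionalClass.EXONIC_OVERLAP_ANTISENSE,
    PositionalClass.INTRONIC_SENSE,
    PositionalClass.INTRONIC_ANTISENSE,
    PositionalClass.GENE_IN_LNCRNA_INTRON,
    PositionalClass.UPSTREAM_1KB_SENSE,
    PositionalClass.UPSTREAM_1KB_ANTISENSE,
    PositionalClass.DOWNSTREAM_1KB_SENSE,
    PositionalClass.DOWNSTREAM_1KB_ANTISENSE,
    PositionalClass.BIDIRECTIONAL_PROMOTER_SHARED,
    PositionalClass.INTERGENIC_GT1KB,
)

BIDIRECTIONAL_TSS_WINDOW = 500  # bp between divergent TSSs sharing a promoter


@dataclass(frozen=True)
class NearestGeneReport:
    lncrna_id: str
    positional_class: PositionalClass
    nearest_gene_id: str | None
    distance: float  # bp; 0 if overlapping; +inf when no gene on the chromosome


def _span_gap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Minimal gap between two half-open spans; 0 when they overlap or touch."""
    if a_start < b_end and b_start < a_end:
        return 0
    return max(a_start - b_end, b_start - a_end, 0)


def _classify_vs_gene(
    lnc: TranscriptModel,
    gene_txs: list[TranscriptModel],
    gene_start: int,
    gene_end: int,
    gene_strand: str,
    window: int,
) -> PositionalClass | None:
    """Eligible class of one lncRNA against one gene, or None when unrelated."""
    same_strand = lnc.strand == gene_strand

    # exonic overlap against any transcript of the gene
    for tx in gene_txs:
        for ls, le in lnc.exons:
            for gs, ge in tx.exons:
                if ls < ge and gs < le:
                    return (
                        PositionalClass.EXONIC_OVERLAP_SENSE
                        if same_strand
                        else PositionalClass.EXONIC_OVERLAP_ANTISENSE
                    )

    # lncRNA entirely within one intron of a transcript of the gene
    for tx in gene_txs:
        for a, b in tx.introns:
            if a <= lnc.start and lnc.end <= b:
                return (
                    PositionalClass.INTRONIC_SENSE
                    if same_strand
                    else PositionalClass.INTRONIC_ANTISENSE
                )

    # gene entirely within one intron of the lncRNA
    for a, b in lnc.introns:
        if a <= gene_start and gene_end <= b:
            return PositionalClass.GENE_IN_LNCRNA_INTRON

    gap = _span_gap(lnc.start, lnc.end, gene_start, gene_end)
    if gap == 0:
        # spans overlap without exonic overlap or full intron containment
        # (e.g. the lncRNA straddles a gene boundary); resolved by which side
        # of the gene the lncRNA midpoint falls on
        mid = (lnc.start + lnc.end) / 2
        gene_mid = (gene_start + gene_end) / 2
        lnc_is_left = mid < gene_mid
        upstream = lnc_is_left if gene_strand == "+" else not lnc_is_left
        if upstream:
            return (
                PositionalClass.UPSTREAM_1KB_SENSE
                if same_strand
                else PositionalClass.UPSTREAM_1KB_ANTISENSE
            )
        return (
            PositionalClass.DOWNSTREAM_1KB_SENSE
            if same_strand
            else PositionalClass.DOWNSTREAM_1KB_ANTISENSE
        )

    if gap > window:
        return None

    # within 1 kb on one side: upstream vs downstream on the gene's strand
    lnc_is_left = lnc.end <= gene_start
    upstream = lnc_is_left if gene_strand == "+" else not lnc_is_left
    if upstream:
        if same_strand:
            return PositionalClass.UPSTREAM_1KB_SENSE
        # divergent pair; a tight TSS-to-TSS gap marks a shared promoter
        if gap <= BIDIRECTIONAL_TSS_WINDOW:
            return PositionalClass.BIDIRECTIONAL_PROMOTER_SHARED
        return PositionalClass.UPSTREAM_1KB_ANTISENSE
    return (
        PositionalClass.DOWNSTREAM_1KB_SENSE
        if same_strand
        else PositionalClass.DOWNSTREAM_1KB_ANTISENSE
    )


def classify_position(
    lncrna: TranscriptModel, coding: AnnotationSet, window: int = 1000
) -> NearestGeneReport:
    """Classify a lncRNA relative to the protein-coding annotation.

    Evaluates every coding gene on the lncRNA's chromosome, picks the most
    specific eligible class (nearest gene breaks ties), and reports the
    classifying gene with its minimal span gap.  A lncRNA on a chromosome
    with no coding gene is reported intergenic at infinite distance.
    """
    if len(coding) == 0:
        raise ValueError("coding annotation is empty")
    gene_ids = sorted({coding.gene_of[t.id] for t in coding.by_chrom(lncrna.chrom)})
    if not gene_ids:
        logger.warning("lncRNA %s: chromosome %s absent from coding annotation", lncrna.id, lncrna.chrom)
        return NearestGeneReport(lncrna.id, PositionalClass.INTERGENIC_GT1KB, None, math.inf)

    best: tuple[int, int, str] | None = None  # (precedence rank, gap, gene_id)
    nearest: tuple[int, str] | None = None
    for gid in gene_ids:
        _, gs, ge = coding.gene_span(gid)
        txs = coding.transcripts_of_gene(gid)
        cls = _classify_vs_gene(lncrna, txs, gs, ge, coding.gene_strand(gid), window)
        gap = _span_gap(lncrna.start, lncrna.end, gs, ge)
        if nearest is None or gap < nearest[0]:
            nearest = (gap, gid)
        if cls is not None:
            key = (_PRECEDENCE.index(cls), gap, gid)
            if best is None or key < best:
                best = key
    if best is not None:
        rank, gap, gid = best
        return NearestGeneReport(lncrna.id, _PRECEDENCE[rank], gid, gap)
    assert nearest is not None
    gap, gid = nearest
    return NearestGeneReport(lncrna.id, PositionalClass.INTERGENIC_GT1KB, gid, gap)
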