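"""Exon-chain comparison of assembled transcripts against a reference.

Implements cuffcompare-style class codes restricted to the seven codes the
lncRNA identification cascade uses:

====  =========================================================
code  meaning
====  =========================================================
``=`` identical intron chain (single-exon: same-strand exonic
      overlap with a single-exon reference)
``c`` contained in a reference transcript with matching
      internal splice sites
``j`` novel isoform: same strand, at least one shared intron,
      chain neither matching nor contained
``o`` other same-strand exonic overlap
``x`` exonic overlap on the opposite strand
``i`` entirely within one intron of a reference transcript
      (either strand)
``u`` intergenic: none of the above
====  =========================================================

When several reference transcripts yield different codes the most specific
one wins, with precedence ``=`` > ``c`` > ``j`` > ``o`` > ``x`` > ``i`` > ``u``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .models import AnnotationSet, TranscriptModel

logger = logging.getLogger(__name__)

CODE_PRECEDENCE = ("=", "c", "j", "o", "x", "i", "u")
RETAINED_CODES = frozenset("ioux")
KNOWN_CODES = frozenset("=cj")


@dataclass(frozen=True)
class ClassCodeResult:
    query_id: str
    code: str
    ref_id: str | None

    def __post_init__(self):
        if (self.code == "u") != (self.ref_id is None):
            raise ValueError("ref_id must be None exactly when code is 'u'")


def _exonic_overlap(a: TranscriptModel, b: TranscriptModel) -> bool:
    """True when any exon of a shares >=1 base with any exon of b."""
    for s1, e1 in a.exons:
        for s2, e2 in b.exons:
            if s1 < e2 and s2 < e1:
                return True
    return False


def _contained_with_matching_sites(q: TranscriptModel, r: TranscriptModel) -> bool:
    """Query chain contained in the reference chain.

    Every query exon lies within a reference exon and every query intron is
    exactly a reference intron (so the query is a contiguous sub-chain, with
    possibly truncated terminal exons).
    """
    r_introns = set(r.introns)
    if not set(q.introns) <= r_introns:
        return False
    for qs, qe in q.exons:
        if not any(rs <= qs and qe <= re_ for rs, re_ in r.exons):
            return False
    return True


def _code_for_pair(q: TranscriptModel, r: TranscriptModel) -> str | None:
    """Best class code of query q against a single reference transcript r."""
    if q.chrom != r.chrom:
        return None
    same_strand = q.strand == r.strand
    overlap = _exonic_overlap(q, r)

    if same_strand:
        if len(q.exons) > 1 or len(r.exons) > 1:
            if q.introns == r.introns and overlap:
                return "="
        elif overlap:  # both single-exon
            return "="
        if overlap and _contained_with_matching_sites(q, r):
            return "c"
        if set(q.introns) & set(r.introns):
            return "j"
        if overlap:
            return "o"
    else:
        if overlap:
            return "x"
    # intronic: query span entirely inside one reference intron (any strand)
    for a, b in r.introns:
        if a <= q.start and q.end <= b:
            return "i"
    return None


def assign_class_code(query: TranscriptModel, reference: AnnotationSet) -> ClassCodeResult:
    """Assign the single most specific class code of a query transcript.

    The query is tested against every reference transcript on its
    chromosome; the highest-precedence code wins, and ties on code are
    broken by reference transcript id so the result never depends on
    iteration order.
    """
    best_rank = len(CODE_PRECEDENCE) - 1  # 'u'
    best_ref: str | None = None
    for ref_tx in reference.by_chrom(query.chrom):
        code = _code_for_pair(query, ref_tx)
        if code is None:
            continue
        rank = CODE_PRECEDENCE.index(code)
        if rank < best_rank or (rank == best_rank and best_ref is not None and ref_tx.id < best_ref):
            best_rank = rank
            best_ref = ref_tx.id
    code = CODE_PRECEDENCE[best_rank]
    return ClassCodeResult(query.id, code, best_ref if code != "u" else None)


@dataclass(frozen=True)
class RemovalRecord:
    transcript_id: str
    reason: str  # 'length' or 'code'
    detail: str


def filter_lncrna_candidates(
    assembled: AnnotationSet,
    reference: AnnotationSet,
    min_length: int = 200,
) -> tuple[list[TranscriptModel], list[RemovalRecord], dict[str, ClassCodeResult]]:
    """Candidate lncRNA filter: length >= 200 nt and class code in {i,o,u,x}.

    Transcripts matching or overlapping known genes on the same strand
    (codes =, c, j) are removed as annotated/coding; each removal is logged
    with its reason.  Returns (retained transcripts, removal log, class
    codes of all queries).
    """
    if len(assembled) == 0:
        logger.warning("empty assembled annotation: nothing to filter")
        return [], [], {}
    retained: list[TranscriptModel] = []
    removals: list[RemovalRecord] = []
    codes: dict[str, ClassCodeResult] = {}
    for tid in sorted(assembled.transcripts):
        tx = assembled.transcripts[tid]
        if tx.length < min_length:
            removals.append(RemovalRecord(tid, "length", f"{tx.length} nt < {min_length}"))
            continue
        res = assign_class_code(tx, reference)
        codes[tid] = res
        if res.code in RETAINED_CODES:
            retained.append(tx)
        else:
            removals.append(RemovalRecord(tid, "code", f"class code '{res.code}' vs {res.ref_id}"))
    return retained, removals, codes


def label_known_novel(
    candidates: list[TranscriptModel], lncrna_reference: AnnotationSet
) -> dict[str, str]:
    """Label candidates 'known' when they match a reference lncRNA (=, c, j)."""
    labels: dict[str, str] = {}
    for tx in candidates:
        res = assign_class_code(tx, lncrna_reference)
        labels[tx.id] = "known" if res.code in KNOWN_CODES else "novel"
    return labels
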