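import numpy as np
import pytest

from bovlnc.annotation_compare import (
    ClassCodeResult,
    assign_class_code,
    filter_lncrna_candidates,
    label_known_novel,
)
from bovlnc.models import AnnotationSet, TranscriptModel

from conftest import random_annotation, random_transcript

# ---------------------------------------------------------------------------
# Brute-force oracle: base-set arithmetic against the code definitions,
# evaluated exhaustively over every (query, reference-transcript) pair.
# ---------------------------------------------------------------------------

PRECEDENCE = "=cjoxiu"


def _bases(tx):
    out = set()
    for s, e in tx.exons:
        out.update(range(s, e))
    return out


def oracle_pair_code(q, r):
    if q.chrom != r.chrom:
        return None
    exonic = bool(_bases(q) & _bases(r))
    if q.strand == r.strand:
        if len(q.exons) == 1 and len(r.exons) == 1:
            if exonic:
                return "="
        elif tuple(q.introns) == tuple(r.introns) and exonic:
            return "="
        contained = exonic and set(q.introns) <= set(r.introns) and all(
            any(rs <= qs and qe <= re for rs, re in r.exons) for qs, qe in q.exons
        )
        if contained:
            return "c"
        if set(q.introns) & set(r.introns):
            return "j"
        if exonic:
            return "o"
    elif exonic:
        return "x"
    if any(a <= q.start and q.end <= b for a, b in r.introns):
        return "i"
    return None


def oracle_assign(q, reference):
    hits = []
    for tx in reference:
        code = oracle_pair_code(q, tx)
        if code is not None:
            hits.append((PRECEDENCE.index(code), tx.id))
    if not hits:
        return ClassCodeResult(q.id, "u", None)
    rank, ref_id = min(hits)
    return ClassCodeResult(q.id, PRECEDENCE[rank], ref_id)


# ---------------------------------------------------------------------------


def _ref(*txs):
    ann = AnnotationSet()
    for i, tx in enumerate(txs):
        ann.add(tx, f"g{i}")
    return ann


class TestClassCodeExamples:
    REF = TranscriptModel("ref1", "chr1", "+", ((100, 300), (500, 800), (1000, 1200)))

    def test_identical_chain_is_equal(self):
        q = TranscriptModel("q", "chr1", "+", self.REF.exons)
        assert assign_class_code(q, _ref(self.REF)).code == "="

    def test_single_exon_inside_intron_is_i(self):
        q = TranscriptModel("q", "chr1", "+", ((350, 450),))
        assert assign_class_code(q, _ref(self.REF)).code == "i"

    def test_opposite_strand_intronic_is_i_not_x(self):
        q = TranscriptModel("q", "chr1", "-", ((350, 450),))
        assert assign_class_code(q, _ref(self.REF)).code == "i"

    def test_opposite_strand_exon_overlap_is_x(self):
        q = TranscriptModel("q", "chr1", "-", ((250, 600),))
        assert assign_class_code(q, _ref(self.REF)).code == "x"

    def test_contained_single_exon_is_c(self):
        q = TranscriptModel("q", "chr1", "+", ((550, 700),))
        assert assign_class_code(q, _ref(self.REF)).code == "c"

    def test_shared_junction_divergent_chain_is_j(self):
        q = TranscriptModel("q", "chr1", "+", ((200, 300), (500, 900)))
        assert assign_class_code(q, _ref(self.REF)).code == "j"

    def test_no_relation_is_u(self):
        q = TranscriptModel("q", "chr1", "+", ((5000, 5400),))
        res = assign_class_code(q, _ref(self.REF))
        assert res.code == "u" and res.ref_id is None

    def test_same_strand_partial_exon_overlap_is_o(self):
        q = TranscriptModel("q", "chr1", "+", ((50, 150),))
        assert assign_class_code(q, _ref(self.REF)).code == "o"


def test_oracle_equivalence_on_random_instances():
    """500 random queries against a random reference match the exhaustive
    per-pair oracle exactly."""
    rng = np.random.default_rng(202)
    mismatches = 0
    for rep in range(5):
        reference = random_annotation(rng)
        for i in range(100):
            q = random_transcript(rng, f"q{rep}_{i}")
            got = assign_class_code(q, reference)
            want = oracle_assign(q, reference)
            if (got.code, got.ref_id) != (want.code, want.ref_id):
                mismatches += 1
    assert mismatches == 0


def test_strand_flip_symmetry():
    """Flipping strands of both query and reference preserves the code."""
    rng = np.random.default_rng(303)
    flip = {"+": "-", "-": "+"}
    for rep in range(50):
        reference = random_annotation(rng, n_genes=6)
        q = random_transcript(rng, f"q{rep}")
        flipped_ref = AnnotationSet()
        for tx in reference:
            flipped_ref.add(
                TranscriptModel(tx.id, tx.chrom, flip[tx.strand], tx.exons),
                reference.gene_of[tx.id],
            )
        q_flip = TranscriptModel(q.id, q.chrom, flip[q.strand], q.exons)
        assert assign_class_code(q, reference).code == assign_class_code(q_flip, flipped_ref).code


def test_insertion_order_does_not_change_result():
    rng = np.random.default_rng(404)
    reference = random_annotation(rng)
    txs = list(reference)
    reversed_ref = AnnotationSet()
    for tx in reversed(txs):
        reversed_ref.add(tx, reference.gene_of[tx.id])
    for i in range(50):
        q = random_transcript(rng, f"q{i}")
        a = assign_class_code(q, reference)
        b = assign_class_code(q, reversed_ref)
        assert (a.code, a.ref_id) == (b.code, b.ref_id)


class TestCandidateFilter:
    def test_short_transcript_removed_for_length(self):
        ref = _ref(TestClassCodeExamples.REF)
        asm = AnnotationSet()
        asm.add(TranscriptModel("short", "chr1", "+", ((5000, 5199),)), "xs")
        retained, removals, _ = filter_lncrna_candidates(asm, ref)
        assert retained == []
        assert removals[0].reason == "length"

    def test_coding_match_removed_for_code(self):
        ref = _ref(TestClassCodeExamples.REF)
        asm = AnnotationSet()
        asm.add(TranscriptModel("copy", "chr1", "+", TestClassCodeExamples.REF.exons), "xc")
        retained, removals, _ = filter_lncrna_candidates(asm, ref)
        assert retained == []
        assert removals[0].reason == "code" and "'='" in removals[0].detail

    def test_intergenic_300nt_retained(self):
        ref = _ref(TestClassCodeExamples.REF)
        asm = AnnotationSet()
        asm.add(TranscriptModel("u1", "chr1", "+", ((9000, 9300),)), "xu")
        retained, removals, codes = filter_lncrna_candidates(asm, ref)
        assert [t.id for t in retained] == ["u1"]
        assert codes["u1"].code == "u"

    def test_empty_assembled_warns_and_returns_empty(self, caplog):
        ref = _ref(TestClassCodeExamples.REF)
        retained, removals, codes = filter_lncrna_candidates(AnnotationSet(), ref)
        assert retained == [] and removals == [] and codes == {}


def test_known_novel_labels_match_planted_truth(sim_data):
    """Candidates planted as known (matching a reference lncRNA by = or c)
    and as novel are labeled exactly per the truth table."""
    reference = sim_data["reference"]
    assembled = sim_data["assembled"]
    truth = sim_data["truth"]
    filter_ref = reference.subset_biotypes(["protein_coding", "other_ncRNA"])
    lnc_ref = reference.subset_biotypes(["lncRNA"])
    retained, _, _ = filter_lncrna_candidates(assembled, filter_ref)
    labels = label_known_novel(retained, lnc_ref)
    want = truth.features.loc[list(labels), "known_label"]
    assert all(labels[i] == want[i] for i in labels)
    assert set(labels.values()) == {"known", "novel"}
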