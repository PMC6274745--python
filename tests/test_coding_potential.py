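import math

import numpy as np
import pytest

from bovlnc.coding_potential import (
    ALL_HEXAMERS,
    CodingPotentialClassifier,
    apply_exclusion_list,
    build_hexamer_tables,
    extract_features,
    fickett_score,
    find_longest_orf,
    find_longest_orf_both_strands,
    hexamer_score,
    train_and_classify,
)
from bovlnc.models import ValidationError
from bovlnc.synthetic_data import _coding_seq, _random_seq

BASES = np.array(list("ACGT"))


def _rand_seq(rng, n):
    return "".join(BASES[rng.integers(0, 4, n)])


# ---------------------------------------------------------------------------
# ORF finder
# ---------------------------------------------------------------------------


def orf_oracle(seq):
    """Enumerate every ATG and scan to the first in-frame stop."""
    best = (0, 0, 0)
    for start in range(len(seq) - 2):
        if seq[start : start + 3] != "ATG":
            continue
        for pos in range(start + 3, len(seq) - 2, 3):
            if seq[pos : pos + 3] in ("TAA", "TAG", "TGA"):
                length = pos + 3 - start
                if length > best[2] or (length == best[2] and start < best[0]):
                    best = (start, pos + 3, length)
                break
    return best


class TestLongestOrf:
    def test_single_complete_orf(self):
        assert find_longest_orf("ATGAAATAA") == (0, 9, 9)

    def test_no_start_codon(self):
        assert find_longest_orf("CCCCCC") == (0, 0, 0)

    def test_start_without_stop_is_not_an_orf(self):
        assert find_longest_orf("ATGAAAAAA") == (0, 0, 0)

    def test_invalid_characters_rejected(self):
        with pytest.raises(ValidationError):
            find_longest_orf("ATGNNNTAA")

    def test_matches_exhaustive_oracle_on_random_sequences(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            seq = _rand_seq(rng, 1000)
            assert find_longest_orf(seq) == orf_oracle(seq)

    def test_both_strands_mode_finds_antisense_orf(self):
        # reverse complement of ATGAAAAAATAA placed on the sense strand
        sense = "ATG" + "AAA" * 20 + "TAA"
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        anti = "".join(comp[b] for b in reversed(sense))
        assert find_longest_orf(anti)[2] < len(sense)
        assert find_longest_orf_both_strands(anti)[2] == len(sense)


# ---------------------------------------------------------------------------
# Fickett TESTCODE
# ---------------------------------------------------------------------------


class TestFickett:
    # deterministic 300-nt sequence; expected value frozen from an
    # independent straight-from-the-tables computation
    SEQ300 = "".join(
        np.array(list("ACGT"))[np.random.default_rng(424242).integers(0, 4, 300)]
    )

    def test_frozen_reference_value(self):
        assert fickett_score(self.SEQ300) == pytest.approx(0.7362, abs=1e-12)

    def test_homopolymer_equals_direct_table_evaluation(self):
        # all-A forces position parameters ~ max/min+1 < 1.1 (lowest bin) and
        # composition A = 1.0 (highest bin), zeros elsewhere
        expected = (
            0.22 * 0.26 + 0.23 * 0.18 + 0.08 * 0.31 + 0.09 * 0.33  # position
            + 0.28 * 0.11 + 0.31 * 0.12 + 0.29 * 0.15 + 0.58 * 0.14  # content
        )
        assert fickett_score("A" * 300) == pytest.approx(expected, abs=1e-12)

    def test_weight_permutation_changes_score(self):
        permuted = {"A": 0.33, "C": 0.26, "G": 0.18, "T": 0.31}
        assert fickett_score(self.SEQ300) != fickett_score(
            self.SEQ300, position_weight=permuted
        )

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValidationError):
            fickett_score("")

    def test_purity(self):
        assert fickett_score(self.SEQ300) == fickett_score(self.SEQ300)


# ---------------------------------------------------------------------------
# Hexamer bias
# ---------------------------------------------------------------------------


class TestHexamer:
    def test_equal_tables_give_zero(self):
        table = {h: 1.0 / len(ALL_HEXAMERS) for h in ALL_HEXAMERS}
        rng = np.random.default_rng(5)
        assert hexamer_score(_rand_seq(rng, 300), table, table) == 0.0

    def test_single_hexamer_ratio_two_gives_ln2(self):
        coding = {h: 1.0 / len(ALL_HEXAMERS) for h in ALL_HEXAMERS}
        noncoding = dict(coding)
        noncoding["ACGTAC"] /= 2.0
        assert hexamer_score("ACGTAC", coding, noncoding) == pytest.approx(math.log(2))

    def test_sequences_from_coding_model_score_positive_on_average(self):
        rng = np.random.default_rng(23)
        coding_train = [_coding_seq(rng, 900) for _ in range(60)]
        noncoding_train = [_rand_seq(rng, 900) for _ in range(60)]
        ct, nt = build_hexamer_tables(coding_train, noncoding_train)
        draws = [hexamer_score(_coding_seq(rng, 900), ct, nt) for _ in range(100)]
        assert np.mean(draws) > 0

    def test_too_short_rejected(self):
        table = {h: 1.0 / len(ALL_HEXAMERS) for h in ALL_HEXAMERS}
        with pytest.raises(ValidationError):
            hexamer_score("ACGTA", table, table)


# ---------------------------------------------------------------------------
# Classifier
# ---------------------------------------------------------------------------


def _training_batch(rng, n_per_class=500, length=(300, 3000)):
    seqs, labels = [], []
    for _ in range(n_per_class):
        ln = int(rng.integers(*length))
        seqs.append(_coding_seq(rng, ln))
        labels.append("coding")
        ln = int(rng.integers(*length))
        seqs.append(_random_seq(rng, ln))
        labels.append("noncoding")
    return seqs, labels


class TestClassifier:
    def test_held_out_accuracy_on_well_separated_classes(self):
        rng = np.random.default_rng(77)
        train_seqs, train_labels = _training_batch(rng, 250)
        test_seqs, test_labels = _training_batch(rng, 250)
        calls = train_and_classify(
            train_seqs, train_labels, {f"t{i}": s for i, s in enumerate(test_seqs)}
        )
        by_id = {c.transcript_id: c.label for c in calls}
        acc = np.mean(
            [by_id[f"t{i}"] == lab for i, lab in enumerate(test_labels)]
        )
        assert acc >= 0.95

    def test_cutoff_boundary_04_counts_as_coding(self):
        clf = CodingPotentialClassifier(cutoff=0.4)

        class Fixed(CodingPotentialClassifier):
            def __init__(self, p):
                super().__init__(cutoff=0.4)
                self._p = p

            def probability(self, seq):
                return self._p

        assert Fixed(0.40).classify({"x": "ACGT"})[0].label == "coding"
        assert Fixed(0.39).classify({"x": "ACGT"})[0].label == "noncoding"

    def test_single_class_training_rejected(self):
        rng = np.random.default_rng(3)
        seqs = [_rand_seq(rng, 300) for _ in range(100)]
        with pytest.raises(ValidationError):
            CodingPotentialClassifier().fit(seqs, ["noncoding"] * 100)

    def test_each_feature_separates_classes(self):
        """Every individual feature has ROC AUC > 0.5 on synthetic data."""
        rng = np.random.default_rng(99)
        coding = [_coding_seq(rng, 800) for _ in range(60)]
        noncoding = [_random_seq(rng, 800) for _ in range(60)]
        ct, nt = build_hexamer_tables(coding, noncoding)
        from sklearn.metrics import roc_auc_score

        feats = np.array(
            [extract_features(s, ct, nt).as_array() for s in coding + noncoding]
        )
        y = np.array([1] * 60 + [0] * 60)
        for j in range(feats.shape[1]):
            assert roc_auc_score(y, feats[:, j]) > 0.5


class TestExclusionList:
    def test_empty_exclusion_is_identity(self):
        assert apply_exclusion_list(["a", "b"], []) == ["a", "b"]

    def test_all_excluded_gives_empty(self):
        assert apply_exclusion_list(["a", "b"], ["a", "b", "c"]) == []

    def test_partial_exclusion(self):
        cands = [f"t{i}" for i in range(10)]
        assert len(apply_exclusion_list(cands, ["t0", "t5", "t9"])) == 7
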