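"""Sequence-based coding-potential assessment.

Four features are extracted per transcript — longest ORF length, ORF
coverage, the Fickett TESTCODE statistic, and an in-frame hexamer usage
log-likelihood ratio — and combined by a logistic regression trained on
labeled coding / non-coding sequences.  Transcripts scoring at or above the
coding-probability cutoff (default 0.4) are removed as potentially coding.

The classifier accepts externally computed scores through the feature
interface, so alternative coding-potential tools can be slotted in.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler

from .models import ValidationError

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")
STOP_CODONS = ("TAA", "TAG", "TGA")
START_CODON = "ATG"


def _check_seq(seq: str, min_len: int = 1) -> str:
    seq = seq.upper()
    if len(seq) < min_len:
        raise ValidationError(f"sequence shorter than {min_len} nt")
    bad = set(seq) - VALID_BASES
    if bad:
        raise ValidationError(f"invalid characters in sequence: {sorted(bad)}")
    return seq


def find_longest_orf(seq: str) -> tuple[int, int, int]:
    """Longest sense-strand ORF (ATG..stop, stop included) over 3 frames.

    Returns (start, end, length) in 0-based half-open coordinates, or
    (0, 0, 0) when no complete ORF exists.  Ties go to the leftmost start.
    """
    seq = _check_seq(seq)
    n = len(seq)
    best = (0, 0, 0)
    for frame in range(3):
        start: int | None = None
        for pos in range(frame, n - 2, 3):
            codon = seq[pos : pos + 3]
            if start is None:
                if codon == START_CODON:
                    start = pos
            elif codon in STOP_CODONS:
                length = pos + 3 - start
                if length > best[2] or (length == best[2] and best[2] and start < best[0]):
                    best = (start, pos + 3, length)
                start = None
    return best


def find_longest_orf_both_strands(seq: str) -> tuple[int, int, int]:
    """Longest ORF on either strand (coordinates on the given strand for sense
    hits; for antisense hits the reverse-complement coordinates are mapped back)."""
    sense = find_longest_orf(seq)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    rc = "".join(comp[b] for b in reversed(_check_seq(seq)))
    anti = find_longest_orf(rc)
    if anti[2] > sense[2]:
        n = len(seq)
        return (n - anti[1], n - anti[0], anti[2])
    return sense


# ---------------------------------------------------------------------------
# Fickett TESTCODE
# ---------------------------------------------------------------------------
# Classic lookup tables: for each base, the position-asymmetry parameter
# max(frame counts)/(min(frame counts)+1) and the composition fraction are
# binned through these thresholds and mapped to probabilities, then combined
# with per-base weights.

_POSITION_PARA = (1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0)
_POSITION_PROB = {
    "A": (0.94, 0.68, 0.84, 0.93, 0.58, 0.68, 0.45, 0.34, 0.20, 0.22),
    "C": (0.80, 0.70, 0.70, 0.81, 0.66, 0.48, 0.51, 0.33, 0.30, 0.23),
    "G": (0.90, 0.88, 0.74, 0.64, 0.53, 0.48, 0.27, 0.16, 0.08, 0.08),
    "T": (0.97, 0.97, 0.91, 0.68, 0.69, 0.44, 0.54, 0.20, 0.09, 0.09),
}
_POSITION_WEIGHT = {"A": 0.26, "C": 0.18, "G": 0.31, "T": 0.33}

_CONTENT_PARA = (0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.19, 0.17, 0.0)
_CONTENT_PROB = {
    "A": (0.28, 0.49, 0.44, 0.55, 0.62, 0.49, 0.67, 0.65, 0.81, 0.21),
    "C": (0.82, 0.64, 0.51, 0.64, 0.59, 0.59, 0.43, 0.44, 0.39, 0.31),
    "G": (0.40, 0.54, 0.47, 0.64, 0.61, 0.73, 0.41, 0.41, 0.33, 0.29),
    "T": (0.28, 0.24, 0.39, 0.40, 0.55, 0.75, 0.56, 0.69, 0.51, 0.58),
}
_CONTENT_WEIGHT = {"A": 0.11, "C": 0.12, "G": 0.15, "T": 0.14}


def _lookup(value: float, para: Sequence[float], prob: Sequence[float]) -> float:
    for threshold, p in zip(para, prob):
        if value >= threshold:
            return p
    return prob[-1]


def fickett_score(
    seq: str,
    *,
    position_weight: Mapping[str, float] | None = None,
    content_weight: Mapping[str, float] | None = None,
) -> float:
    """Fickett TESTCODE statistic.

    Position asymmetry and base composition for each of A, C, G, T are
    mapped through the published lookup tables to coding probabilities and
    combined with the published weights.  Weight mappings are exposed for
    sensitivity checks only.
    """
    seq = _check_seq(seq, min_len=1)
    if len(seq) < 200:
        logger.warning("fickett_score on a %d nt sequence; <200 nt is unreliable", len(seq))
    pw = dict(_POSITION_WEIGHT if position_weight is None else position_weight)
    cw = dict(_CONTENT_WEIGHT if content_weight is None else content_weight)
    n = len(seq)
    score = 0.0
    for base in "ACGT":
        frame_counts = [seq[f::3].count(base) for f in range(3)]
        position_param = max(frame_counts) / (min(frame_counts) + 1.0)
        content_param = seq.count(base) / n
        score += _lookup(position_param, _POSITION_PARA, _POSITION_PROB[base]) * pw[base]
        score += _lookup(content_param, _CONTENT_PARA, _CONTENT_PROB[base]) * cw[base]
    return score


# ---------------------------------------------------------------------------
# Hexamer usage bias
# ---------------------------------------------------------------------------

ALL_HEXAMERS = tuple("".join(p) for p in itertools.product("ACGT", repeat=6))


def build_hexamer_tables(
    coding_seqs: Iterable[str], noncoding_seqs: Iterable[str], pseudocount: float = 1.0
) -> tuple[dict[str, float], dict[str, float]]:
    """In-frame hexamer frequency tables (pseudocount-smoothed) for the two classes."""

    def table(seqs: Iterable[str]) -> dict[str, float]:
        counts = dict.fromkeys(ALL_HEXAMERS, pseudocount)
        for seq in seqs:
            seq = _check_seq(seq)
            for i in range(0, len(seq) - 5, 3):
                counts[seq[i : i + 6]] += 1
        total = sum(counts.values())
        return {h: c / total for h, c in counts.items()}

    return table(coding_seqs), table(noncoding_seqs)


def hexamer_score(
    seq: str,
    coding_table: Mapping[str, float],
    noncoding_table: Mapping[str, float],
) -> float:
    """Mean natural-log likelihood ratio over in-frame hexamers (step 3, frame 0)."""
    seq = _check_seq(seq, min_len=6)
    total = 0.0
    k = 0
    for i in range(0, len(seq) - 5, 3):
        h = seq[i : i + 6]
        total += math.log(coding_table[h] / noncoding_table[h])
        k += 1
    return total / k


# ---------------------------------------------------------------------------
# Feature extraction and logistic classification
# ---------------------------------------------------------------------------

FEATURE_NAMES = ("orf_length", "orf_coverage", "fickett", "hexamer")


@dataclass(frozen=True)
class CodingFeatures:
    orf_length: int
    orf_coverage: float
    fickett: float
    hexamer: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.orf_length, self.orf_coverage, self.fickett, self.hexamer], dtype=float
        )


@dataclass(frozen=True)
class CodingCall:
    transcript_id: str
    probability: float
    label: str  # 'coding' or 'noncoding'


def extract_features(
    seq: str,
    coding_table: Mapping[str, float],
    noncoding_table: Mapping[str, float],
    *,
    both_strands: bool = False,
) -> CodingFeatures:
    seq = _check_seq(seq)
    orf = find_longest_orf_both_strands(seq) if both_strands else find_longest_orf(seq)
    return CodingFeatures(
        orf_length=orf[2],
        orf_coverage=orf[2] / len(seq),
        fickett=fickett_score(seq),
        hexamer=hexamer_score(seq, coding_table, noncoding_table),
    )


class CodingPotentialClassifier:
    """Logistic regression on (ORF length, ORF coverage, Fickett, hexamer).

    Features are standardized before fitting.  A transcript with coding
    probability >= ``cutoff`` is called coding; the boundary value itself
    counts as coding, a conservative removal of possibly coding transcripts.
    """

    def __init__(self, cutoff: float = 0.4, both_strands: bool = False):
        if not 0.0 < cutoff < 1.0:
            raise ValidationError("cutoff must be in (0, 1)")
        self.cutoff = cutoff
        self.both_strands = both_strands
        self._scaler: StandardScaler | None = None
        self._model: LogisticRegression | None = None
        self.coding_table: dict[str, float] | None = None
        self.noncoding_table: dict[str, float] | None = None

    def fit(self, seqs: Sequence[str], labels: Sequence[str]) -> "CodingPotentialClassifier":
        labels = [str(l) for l in labels]
        if set(labels) != {"coding", "noncoding"}:
            raise ValidationError("training set must contain both 'coding' and 'noncoding' labels")
        coding = [s for s, l in zip(seqs, labels) if l == "coding"]
        noncoding = [s for s, l in zip(seqs, labels) if l == "noncoding"]
        self.coding_table, self.noncoding_table = build_hexamer_tables(coding, noncoding)
        X = np.vstack([self._features(s).as_array() for s in seqs])
        y = np.array([1 if l == "coding" else 0 for l in labels])
        self._scaler = StandardScaler().fit(X)
        self._model = LogisticRegression(max_iter=1000).fit(self._scaler.transform(X), y)
        return self

    def _features(self, seq: str) -> CodingFeatures:
        assert self.coding_table is not None and self.noncoding_table is not None
        return extract_features(
            seq, self.coding_table, self.noncoding_table, both_strands=self.both_strands
        )

    def probability(self, seq: str) -> float:
        if self._model is None or self._scaler is None:
            raise ValidationError("classifier not fitted")
        X = self._features(seq).as_array()[None, :]
        return float(self._model.predict_proba(self._scaler.transform(X))[0, 1])

    def classify(self, seqs: Mapping[str, str]) -> list[CodingCall]:
        calls = []
        for tid in sorted(seqs):
            p = self.probability(seqs[tid])
            calls.append(CodingCall(tid, p, "coding" if p >= self.cutoff else "noncoding"))
        return calls


def train_and_classify(
    train_seqs: Sequence[str],
    train_labels: Sequence[str],
    candidates: Mapping[str, str],
    cutoff: float = 0.4,
    both_strands: bool = False,
) -> list[CodingCall]:
    """Fit the coding-potential model and classify candidate transcripts.

    Requires at least 50 training sequences per label.
    """
    for lab in ("coding", "noncoding"):
        n = sum(1 for l in train_labels if l == lab)
        if n < 50:
            raise ValidationError(f"need >=50 '{lab}' training sequences, got {n}")
    clf = CodingPotentialClassifier(cutoff=cutoff, both_strands=both_strands)
    clf.fit(train_seqs, train_labels)
    return clf.classify(candidates)


def apply_exclusion_list(candidates: Iterable[str], exclusions: Iterable[str]) -> list[str]:
    """Remove candidates appearing in an external exclusion list (e.g. protein hits)."""
    excl = set(exclusions)
    cand = list(candidates)
    retained = sorted(c for c in cand if c not in excl)
    removed = len(cand) - len(retained)
    if removed:
        logger.info("exclusion list removed %d of %d candidates", removed, len(cand))
    if cand and not retained:
        logger.warning("exclusion list removed every candidate")
    return retained
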