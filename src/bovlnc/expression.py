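"""Count normalization, expression filtering, FPKM and descriptive summaries.

Normalization uses the median-of-ratios size factors familiar from count
based differential-expression tools: per-feature geometric means across
libraries (features with any zero excluded), then the per-library median of
count/geomean ratios.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class CountMatrix:
    """Fragment counts (features x libraries) plus per-feature lengths in nt."""

    counts: pd.DataFrame
    lengths: pd.Series

    def __post_init__(self):
        if (self.counts.values < 0).any():
            raise ValidationError("count matrix contains negative entries")
        if not np.allclose(self.counts.values, np.round(self.counts.values)):
            raise ValidationError("count matrix must be integer-valued")
        self.lengths = self.lengths.reindex(self.counts.index)
        if self.lengths.isna().any():
            missing = self.lengths[self.lengths.isna()].index.tolist()[:5]
            raise ValidationError(f"missing lengths for features {missing}")
        if (self.lengths <= 0).any():
            raise ValidationError("feature lengths must be positive")

    @property
    def features(self) -> pd.Index:
        return self.counts.index

    @property
    def libraries(self) -> pd.Index:
        return self.counts.columns

    def subset(self, feature_ids) -> "CountMatrix":
        ids = [f for f in feature_ids if f in self.counts.index]
        return CountMatrix(self.counts.loc[ids], self.lengths.loc[ids])


def size_factors(counts: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios library size factors.

    Features with a zero count in any library are excluded from the
    geometric-mean reference; at least one all-nonzero feature is required.
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    vals = mat.values.astype(float)
    all_nonzero = (vals > 0).all(axis=1)
    if not all_nonzero.any():
        raise ValidationError(
            "no feature has nonzero counts in every library; filter the matrix first"
        )
    ref = vals[all_nonzero]
    geomean = np.exp(np.log(ref).mean(axis=1))
    # median taken on the linear ratio scale (an even count averages the two
    # central ratios, which differs from exponentiating a log-scale median)
    factors = np.median(ref / geomean[:, None], axis=0)
    return pd.Series(factors, index=mat.columns, name="size_factor")


def normalized_counts(counts: CountMatrix | pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    return mat / factors


def expressed_filter(
    counts: CountMatrix | pd.DataFrame,
    factors: pd.Series,
    min_norm_count: float = 5.0,
    min_lib_frac: float = 0.10,
) -> list:
    """Truly-expressed filter: normalized count >= ``min_norm_count`` in at
    least ``ceil(min_lib_frac * n_libraries)`` libraries.

    With 36 libraries and the 10% rule the threshold is 4 libraries.
    """
    norm = normalized_counts(counts, factors)
    n_required = math.ceil(min_lib_frac * norm.shape[1])
    ok = (norm >= min_norm_count).sum(axis=1) >= n_required
    return list(norm.index[ok])


def fpkm(counts: CountMatrix, factors: pd.Series | None = None) -> tuple[pd.DataFrame, pd.Series]:
    """FPKM matrix and per-feature means.

    FPKM_ij = count_ij * 1e9 / (N_j * L_i) with N_j the total counted
    fragments of library j (the column sum of the matrix) and L_i the
    transcript length in nt.  ``factors`` is accepted for interface symmetry
    but FPKM uses raw library totals.
    """
    totals = counts.counts.sum(axis=0).astype(float)
    if (totals == 0).any():
        bad = totals.index[totals == 0].tolist()
        raise ValidationError(f"zero total fragments in libraries {bad}")
    mat = counts.counts.values * 1e9 / (totals.values[None, :] * counts.lengths.values[:, None])
    df = pd.DataFrame(mat, index=counts.features, columns=counts.libraries)
    return df, df.mean(axis=1).rename("mean_fpkm")


LENGTH_BINS = ((200, 999), (1000, 2499), (2500, None))


@dataclass
class ExpressionSummary:
    top_expressed: pd.DataFrame
    length_histogram: pd.DataFrame
    transcripts_per_gene: pd.Series
    per_chromosome: pd.Series


def summarize(
    mean_fpkm: pd.Series,
    labels: dict[str, str],
    lengths: pd.Series,
    chroms: dict[str, str],
    gene_of: dict[str, str],
    top_k: int = 15,
) -> ExpressionSummary:
    """Descriptive summaries of an identified lncRNA set.

    * top-k transcripts by mean FPKM within each known/novel label, ties
      broken by transcript id;
    * transcript length histogram over the bins 200-999, 1000-2499, >=2500 nt;
    * transcripts-per-gene distribution;
    * per-chromosome transcript counts.
    """
    rows = []
    for label in sorted(set(labels.values())):
        ids = [i for i in mean_fpkm.index if labels.get(i) == label]
        ranked = sorted(ids, key=lambda i: (-mean_fpkm[i], i))[:top_k]
        for rank, tid in enumerate(ranked, 1):
            rows.append({"label": label, "rank": rank, "transcript_id": tid, "mean_fpkm": mean_fpkm[tid]})
    top = pd.DataFrame(rows, columns=["label", "rank", "transcript_id", "mean_fpkm"])

    hist_rows = []
    n = len(lengths)
    for lo, hi in LENGTH_BINS:
        if hi is None:
            count = int((lengths >= lo).sum())
            name = f">={lo}"
        else:
            count = int(((lengths >= lo) & (lengths <= hi)).sum())
            name = f"{lo}-{hi}"
        hist_rows.append({"bin": name, "count": count, "pct": 100.0 * count / n if n else 0.0})
    hist = pd.DataFrame(hist_rows, columns=["bin", "count", "pct"])

    per_gene = pd.Series(list(gene_of.values())).value_counts()
    tx_per_gene = per_gene.value_counts().sort_index().rename("n_genes")
    tx_per_gene.index.name = "n_transcripts"

    chrom_counts = pd.Series(list(chroms.values())).value_counts().sort_index().rename("n_transcripts")
    chrom_counts.index.name = "chrom"

    return ExpressionSummary(top, hist, tx_per_gene, chrom_counts)
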