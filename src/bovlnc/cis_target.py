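"""Windowed correlation-based cis-target calling.

Protein-coding genes whose span lies within 50 kb of a lncRNA are candidate
cis targets; a pair is called when the Pearson correlation of their
expression across the libraries of one treatment exceeds 0.7 (strict).
Expression values are log2(size-factor-normalized count + 1) by default.
P-values come from the exact t transform of r with n - 2 degrees of
freedom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .expression import CountMatrix, normalized_counts, size_factors
from .models import AnnotationSet, TranscriptModel, ValidationError

logger = logging.getLogger(__name__)

CIS_WINDOW = 50_000
CIS_R_THRESHOLD = 0.7


@dataclass(frozen=True)
class CisPair:
    lncrna_id: str
    gene_id: str
    r: float
    p: float
    distance: int
    chrom: str
    gene_start: int
    gene_end: int
    treatment: str | None = None


def _span_gap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    if a_start < b_end and b_start < a_end:
        return 0
    return max(a_start - b_end, b_start - a_end, 0)


def window_candidates(
    lncrna: TranscriptModel, coding: AnnotationSet, window: int = CIS_WINDOW
) -> list[tuple[str, int]]:
    """Coding genes whose span overlaps [start - window, end + window].

    Returns (gene_id, distance) sorted by distance then gene id; the window
    boundary is inclusive (a gene exactly ``window`` bp away is a candidate).
    """
    out = []
    seen = set()
    for tx in coding.by_chrom(lncrna.chrom):
        gid = coding.gene_of[tx.id]
        if gid in seen:
            continue
        seen.add(gid)
        _, gs, ge = coding.gene_span(gid)
        gap = _span_gap(lncrna.start, lncrna.end, gs, ge)
        if gap <= window:
            out.append((gid, gap))
    return sorted(out, key=lambda t: (t[1], t[0]))


def pearson_p_from_r(r: float, n: int) -> float:
    """Two-sided p-value of a sample Pearson r at sample size n via Student t."""
    if n < 3:
        raise ValidationError("need n >= 3 for a correlation p-value")
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def pearson_with_p(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with its two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D arrays of equal length")
    if x.size < 3:
        raise ValidationError("need n >= 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("constant vector: correlation undefined")
    r = float(stats.pearsonr(x, y).statistic)
    return r, pearson_p_from_r(r, x.size)


def expression_for_correlation(
    counts: CountMatrix, factors: pd.Series, scale: str = "log2norm"
) -> pd.DataFrame:
    """Expression values used for cis correlation.

    ``log2norm`` (default): log2(normalized count + 1); ``norm``: normalized
    counts on the linear scale.
    """
    norm = normalized_counts(counts, factors)
    if scale == "log2norm":
        return np.log2(norm + 1.0)
    if scale == "norm":
        return norm
    raise ValidationError(f"unknown correlation scale {scale!r}")


def call_cis_pairs(
    lncrnas: list[TranscriptModel],
    coding: AnnotationSet,
    counts: CountMatrix,
    design: pd.DataFrame,
    treatment: str,
    factors: pd.Series | None = None,
    window: int = CIS_WINDOW,
    r_threshold: float = CIS_R_THRESHOLD,
    scale: str = "log2norm",
    restrict_lncrnas: set[str] | None = None,
) -> list[CisPair]:
    """Call cis pairs within one treatment.

    A pair is called iff the gene span is within ``window`` bp of the lncRNA
    and the Pearson correlation of their expression over the treatment's
    libraries is strictly greater than ``r_threshold``.  Pairs with a
    constant expression vector are flagged and skipped.
    """
    libs = design.index[design["treatment"] == treatment]
    if factors is None:
        factors = size_factors(counts)
    expr = expression_for_correlation(counts, factors, scale=scale)[libs]
    pairs: list[CisPair] = []
    for lnc in sorted(lncrnas, key=lambda t: t.id):
        lnc_gene = None
        if lnc.id in expr.index:
            lnc_gene = lnc.id
        if lnc_gene is None or (restrict_lncrnas is not None and lnc.id not in restrict_lncrnas):
            continue
        x = expr.loc[lnc_gene].values
        if np.ptp(x) == 0:
            logger.warning("lncRNA %s: constant expression in %s, skipped", lnc.id, treatment)
            continue
        for gid, gap in window_candidates(lnc, coding, window=window):
            if gid not in expr.index:
                continue
            y = expr.loc[gid].values
            if np.ptp(y) == 0:
                logger.warning("gene %s: constant expression in %s, skipped", gid, treatment)
                continue
            r, p = pearson_with_p(x, y)
            if r > r_threshold:
                chrom, gs, ge = coding.gene_span(gid)
                pairs.append(CisPair(lnc.id, gid, r, p, gap, chrom, gs, ge, treatment))
    return pairs


def cis_pairs_frame(pairs: list[CisPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "treatment": p.treatment,
                "lncrna_id": p.lncrna_id,
                "gene_id": p.gene_id,
                "correlation": p.r,
                "p_value": p.p,
                "chromosome": p.chrom,
                "gene_start": p.gene_start,
                "gene_end": p.gene_end,
                "distance": p.distance,
            }
            for p in pairs
        ]
    )
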