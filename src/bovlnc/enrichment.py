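"""Hypergeometric over-representation analysis of gene lists.

Each term is tested with the upper-tail hypergeometric probability
P(X >= k) for X ~ Hypergeometric(N, K, n) where N is the universe size, K
the term's genes in the universe, n the input list size and k the overlap.
Benjamini-Hochberg adjustment is applied within each ontology source.  The
dual significance regime mirrors common enrichment practice: GO sources at
adjusted p <= 0.05, pathway sources at raw p < 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from scipy.stats import hypergeom

from .diffexpr import bh_adjust
from .models import ValidationError

logger = logging.getLogger(__name__)

GO_SOURCES = ("GO_BP", "GO_CC", "GO_MF")
PATHWAY_SOURCE = "PATHWAY"
VALID_SOURCES = GO_SOURCES + (PATHWAY_SOURCE,)


@dataclass(frozen=True)
class TermAnnotation:
    term_id: str
    term_name: str
    source: str
    genes: frozenset[str]

    def __post_init__(self):
        if self.source not in VALID_SOURCES:
            raise ValidationError(f"unknown ontology source {self.source!r}")


@dataclass(frozen=True)
class EnrichmentRow:
    term_id: str
    term_name: str
    source: str
    k: int
    K: int
    n: int
    N: int
    p: float
    p_fdr: float
    significant: bool


def hypergeom_enrich(
    input_genes,
    universe,
    terms: list[TermAnnotation],
    go_fdr: float = 0.05,
    pathway_p: float = 0.05,
) -> list[EnrichmentRow]:
    """Hypergeometric enrichment of an input gene list against term sets.

    Terms with no universe genes or no overlap get p = 1 and are never
    significant.  Significance: GO sources at BH-adjusted p <= ``go_fdr``,
    pathway source at raw p < ``pathway_p``.
    """
    input_set = set(input_genes)
    universe_set = set(universe)
    if not terms:
        raise ValidationError("no terms supplied")
    offenders = sorted(input_set - universe_set)
    if offenders:
        raise ValidationError(f"input genes absent from universe: {offenders}")
    N = len(universe_set)
    n = len(input_set)

    raw: list[tuple[TermAnnotation, int, int, float]] = []
    for term in terms:
        term_in_universe = term.genes & universe_set
        if term.genes - universe_set:
            logger.debug("term %s: %d genes outside universe ignored",
                         term.term_id, len(term.genes - universe_set))
        K = len(term_in_universe)
        k = len(term_in_universe & input_set)
        if K == 0 or k == 0:
            p = 1.0
        else:
            p = float(hypergeom.sf(k - 1, N, K, n))
            p = min(p, 1.0)
        raw.append((term, k, K, p))

    # BH within each ontology source
    p_fdr: dict[int, float] = {}
    for source in sorted({t.source for t, _, _, _ in raw}):
        idx = [i for i, (t, _, _, _) in enumerate(raw) if t.source == source]
        adj = bh_adjust([raw[i][3] for i in idx])
        for i, a in zip(idx, adj):
            p_fdr[i] = float(a)

    rows = []
    for i, (term, k, K, p) in enumerate(raw):
        if k == 0 or K == 0:
            sig = False
        elif term.source == PATHWAY_SOURCE:
            sig = p < pathway_p
        else:
            sig = p_fdr[i] <= go_fdr
        rows.append(
            EnrichmentRow(term.term_id, term.term_name, term.source, k, K, n, N, p, p_fdr[i], sig)
        )
    return rows


def enrichment_frame(rows: list[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term_id": r.term_id,
                "term_name": r.term_name,
                "source": r.source,
                "k": r.k,
                "K": r.K,
                "n": r.n,
                "N": r.N,
                "p_value": r.p,
                "p_fdr": r.p_fdr,
                "significant": r.significant,
            }
            for r in rows
        ]
    )


def read_term_table(path) -> list[TermAnnotation]:
    """Read a gene->term TSV (gene_id, term_id, term_name, source)."""
    df = pd.read_csv(path, sep="\t")
    terms = []
    for (tid, name, source), grp in df.groupby(["term_id", "term_name", "source"], sort=True):
        terms.append(TermAnnotation(tid, name, source, frozenset(grp["gene_id"])))
    return terms
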