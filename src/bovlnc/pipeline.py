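"""End-to-end orchestration of the identification and quantification stages.

``run_identify`` wires the candidate cascade in order: length filter ->
class-code filter -> coding-potential filter -> exclusion list ->
known/novel labeling -> positional classification, logging per-stage counts
(in = removed + retained at every stage).  ``run_quantify`` continues with
the expression filter, FPKM, differential expression per treatment and
timepoint contrast, cis-target calling (all lncRNAs and the DE subset) and
term enrichment.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field

import pandas as pd
import yaml

from .annotation_compare import filter_lncrna_candidates, label_known_novel
from .cis_target import CisPair, call_cis_pairs, cis_pairs_frame
from .coding_potential import CodingCall, apply_exclusion_list, train_and_classify
from .diffexpr import CONTRAST_DAYS, DEResult, de_results_frame, nb_wald_test
from .enrichment import TermAnnotation, enrichment_frame, hypergeom_enrich
from .expression import CountMatrix, expressed_filter, fpkm, size_factors
from .models import AnnotationSet, TranscriptModel, ValidationError
from .positional import NearestGeneReport, classify_position

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass(frozen=True)
class PipelineConfig:
    """All thresholds of the pipeline, overridable but defaulting to the
    standard cascade values."""

    min_length: int = 200
    coding_cutoff: float = 0.4
    expr_min_norm_count: float = 5.0
    expr_min_lib_frac: float = 0.10
    de_padj: float = 0.1
    cis_window: int = 50_000
    cis_r: float = 0.7
    go_fdr: float = 0.05
    kegg_p: float = 0.05
    seed: int = 0
    correlation_scale: str = "log2norm"
    orf_both_strands: bool = False

    def validate(self) -> None:
        if self.min_length <= 0 or self.cis_window <= 0:
            raise ValidationError("length and window thresholds must be positive")
        for name in ("coding_cutoff", "expr_min_lib_frac", "de_padj", "go_fdr", "kegg_p"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValidationError(f"{name} must lie in (0, 1]")
        if not 0.0 < self.cis_r < 1.0:
            raise ValidationError("cis_r must lie in (0, 1)")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass(frozen=True)
class StageCount:
    stage: str
    n_in: int
    n_removed: int
    n_retained: int

    def __post_init__(self):
        if self.n_in != self.n_removed + self.n_retained:
            raise ValidationError(f"stage {self.stage}: {self.n_in} != {self.n_removed} + {self.n_retained}")


@dataclass
class IdentifyResult:
    lncrnas: list[TranscriptModel]
    stage_counts: list[StageCount]
    class_codes: pd.DataFrame
    removals: pd.DataFrame
    coding_calls: list[CodingCall]
    known_novel: dict[str, str]
    positional: list[NearestGeneReport]

    def positional_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "lncrna_id": r.lncrna_id,
                    "positional_class": r.positional_class.value,
                    "nearest_gene_id": r.nearest_gene_id or "",
                    "distance": r.distance,
                }
                for r in self.positional
            ]
        )


def run_identify(
    assembled: AnnotationSet,
    reference: AnnotationSet,
    candidate_seqs: dict[str, str],
    train_seqs: list[str],
    train_labels: list[str],
    exclusions: set[str] | None = None,
    config: PipelineConfig | None = None,
) -> IdentifyResult:
    """Run the lncRNA identification cascade.

    ``reference`` carries both the gene annotation used for filtering and
    positional classification (biotypes ``protein_coding`` / ``other_ncRNA``)
    and the known-lncRNA annotation (biotype ``lncRNA``) used for
    known/novel labeling.
    """
    cfg = config or PipelineConfig()
    cfg.validate()
    exclusions = exclusions or set()
    stage_counts: list[StageCount] = []

    filter_reference = reference.subset_biotypes(["protein_coding", "other_ncRNA"])
    lncrna_reference = reference.subset_biotypes(["lncRNA"])
    coding_reference = reference.subset_biotypes(["protein_coding"])

    try:
        retained, removals, codes = filter_lncrna_candidates(
            assembled, filter_reference, min_length=cfg.min_length
        )
    except Exception as e:  # pragma: no cover
        raise StageError("class_code_filter", e) from e
    n_total = len(assembled)
    n_len = sum(1 for r in removals if r.reason == "length")
    n_code = sum(1 for r in removals if r.reason == "code")
    stage_counts.append(StageCount("length_filter", n_total, n_len, n_total - n_len))
    stage_counts.append(StageCount("class_code_filter", n_total - n_len, n_code, len(retained)))
    logger.info("length filter removed %d, class-code filter removed %d of %d", n_len, n_code, n_total)

    try:
        ids = sorted(t.id for t in retained)
        missing = [i for i in ids if i not in candidate_seqs]
        if missing:
            raise ValidationError(f"no sequence for candidates {missing[:5]}")
        calls = train_and_classify(
            train_seqs,
            train_labels,
            {i: candidate_seqs[i] for i in ids},
            cutoff=cfg.coding_cutoff,
            both_strands=cfg.orf_both_strands,
        )
    except StageError:
        raise
    except Exception as e:
        raise StageError("coding_potential", e) from e
    noncoding_ids = {c.transcript_id for c in calls if c.label == "noncoding"}
    stage_counts.append(
        StageCount("coding_potential", len(ids), len(ids) - len(noncoding_ids), len(noncoding_ids))
    )

    surviving = apply_exclusion_list(sorted(noncoding_ids), exclusions)
    stage_counts.append(
        StageCount("exclusion_list", len(noncoding_ids), len(noncoding_ids) - len(surviving), len(surviving))
    )

    lncrnas = [t for t in retained if t.id in set(surviving)]
    try:
        known_novel = label_known_novel(lncrnas, lncrna_reference)
        positional = [classify_position(t, coding_reference) for t in sorted(lncrnas, key=lambda t: t.id)]
    except Exception as e:
        raise StageError("classification", e) from e

    code_frame = pd.DataFrame(
        [{"query_id": q, "code": c.code, "ref_id": c.ref_id or ""} for q, c in sorted(codes.items())]
    )
    removal_frame = pd.DataFrame(
        [{"transcript_id": r.transcript_id, "reason": r.reason, "detail": r.detail} for r in removals]
    )
    return IdentifyResult(
        lncrnas=sorted(lncrnas, key=lambda t: t.id),
        stage_counts=stage_counts,
        class_codes=code_frame,
        removals=removal_frame,
        coding_calls=calls,
        known_novel=known_novel,
        positional=positional,
    )


@dataclass
class QuantifyResult:
    expressed_ids: list[str]
    factors: pd.Series
    fpkm_mean: pd.Series
    de: pd.DataFrame
    de_overlap: pd.DataFrame
    cis_all: pd.DataFrame
    cis_de: pd.DataFrame
    enrichment: pd.DataFrame


def de_overlap_table(de: pd.DataFrame) -> pd.DataFrame:
    """Venn-style table of significant features across contrasts, per treatment."""
    rows = []
    sig = de[de["significant"]]
    for treatment, grp in sig.groupby("treatment"):
        sets = {
            f"{a} vs {b}": set(grp[(grp["dayA"] == a) & (grp["dayB"] == b)]["feature_id"])
            for a, b in CONTRAST_DAYS
        }
        names = list(sets)
        for i, n1 in enumerate(names):
            rows.append({"treatment": treatment, "cell": n1, "n": len(sets[n1]),
                         "features": ",".join(sorted(sets[n1]))})
            for n2 in names[i + 1:]:
                inter = sets[n1] & sets[n2]
                rows.append({"treatment": treatment, "cell": f"({n1}) & ({n2})",
                             "n": len(inter), "features": ",".join(sorted(inter))})
        all3 = set.intersection(*sets.values()) if sets else set()
        rows.append({"treatment": treatment, "cell": "all three", "n": len(all3),
                     "features": ",".join(sorted(all3))})
    return pd.DataFrame(rows, columns=["treatment", "cell", "n", "features"])


def run_quantify(
    identify: IdentifyResult,
    reference: AnnotationSet,
    counts: CountMatrix,
    design: pd.DataFrame,
    terms: list[TermAnnotation] | None = None,
    config: PipelineConfig | None = None,
) -> QuantifyResult:
    """Expression filter, FPKM, DE, cis targets and enrichment."""
    cfg = config or PipelineConfig()
    cfg.validate()
    coding_reference = reference.subset_biotypes(["protein_coding"])

    try:
        factors = size_factors(counts)
        expressed = expressed_filter(
            counts, factors, min_norm_count=cfg.expr_min_norm_count, min_lib_frac=cfg.expr_min_lib_frac
        )
    except Exception as e:
        raise StageError("expression_filter", e) from e

    lnc_ids = {t.id for t in identify.lncrnas}
    expressed_lnc = [i for i in expressed if i in lnc_ids]
    sub = counts.subset(expressed)
    _, fpkm_mean = fpkm(sub)

    de_frames = []
    treatments = sorted(design["treatment"].unique())
    lnc_counts = counts.subset(expressed_lnc)
    try:
        for treatment in treatments:
            for day_a, day_b in CONTRAST_DAYS:
                res = nb_wald_test(lnc_counts, design, (treatment, day_a, day_b),
                                   factors=factors, de_padj=cfg.de_padj)
                de_frames.append(de_results_frame(res))
    except Exception as e:
        raise StageError("differential_expression", e) from e
    de = pd.concat(de_frames, ignore_index=True) if de_frames else pd.DataFrame()

    expressed_lnc_models = [t for t in identify.lncrnas if t.id in set(expressed_lnc)]
    de_sig_ids = set(de[de["significant"]]["feature_id"]) if len(de) else set()
    cis_all: list[CisPair] = []
    cis_de: list[CisPair] = []
    try:
        for treatment in treatments:
            cis_all.extend(
                call_cis_pairs(expressed_lnc_models, coding_reference, counts, design, treatment,
                               factors=factors, window=cfg.cis_window, r_threshold=cfg.cis_r,
                               scale=cfg.correlation_scale)
            )
            cis_de.extend(
                call_cis_pairs(expressed_lnc_models, coding_reference, counts, design, treatment,
                               factors=factors, window=cfg.cis_window, r_threshold=cfg.cis_r,
                               scale=cfg.correlation_scale, restrict_lncrnas=de_sig_ids)
            )
    except Exception as e:
        raise StageError("cis_target", e) from e

    enr = pd.DataFrame()
    if terms:
        universe = [g for g in coding_reference.genes() if g in set(expressed)]
        input_genes = sorted({p.gene_id for p in cis_all} & set(universe))
        if input_genes:
            rows = hypergeom_enrich(input_genes, universe, terms,
                                    go_fdr=cfg.go_fdr, pathway_p=cfg.kegg_p)
            enr = enrichment_frame(rows)

    return QuantifyResult(
        expressed_ids=expressed,
        factors=factors,
        fpkm_mean=fpkm_mean,
        de=de,
        de_overlap=de_overlap_table(de),
        cis_all=cis_pairs_frame(cis_all),
        cis_de=cis_pairs_frame(cis_de),
        enrichment=enr,
    )
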